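"""End-to-end orchestration: synthetic demo screens and kinetics runs.

Each run executes the staged pipeline (quantify -> ratio -> spatial
normalization -> replicate combination -> control normalization -> hit
calling -> QC) with stage-tagged error reporting, and writes a machine-
readable manifest (parameters, seed, content hash per output) so identical
configurations reproduce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import kinetics as kin
from .normalize import compute_ratio, plate_qc, spatial_normalize
from .quantify import quantify_plate
from .screen import (call_hits, combine_replicates, control_normalize,
                     duplicate_concordance, render_outputs, replicate_pearson)
from .simulate import (KineticsTruth, PlateSpec, default_screen_truth,
                       generate_plate_map, simulate_colony_plates,
                       simulate_growth_curves, simulate_screen_tables)

log = logging.getLogger("riboscreen")

__all__ = ["RunConfig", "StageError", "run_screen", "run_kinetics"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"[{stage}] {detail}")


@dataclass
class RunConfig:
    """Configuration of a screen or kinetics run.

    ``synthetic`` holds generator settings for demo/synthetic runs (strain and
    plate counts, planted-effect counts, whether plate images are rendered and
    quantified or per-colony totals are used directly). File-driven screen
    runs instead point ``measurements`` at quantified per-colony CSVs keyed by
    reporter and replicate.
    """

    outdir: str = "results/run"
    seed: int = 7
    threshold_k: float = 5.0
    smooth_window: int = 13
    growth_floor: float = 0.1
    stationary_t: float = 16.0
    reference_molar: float = 0.0
    timepoint: str = "24h"
    spec: dict = field(default_factory=dict)
    synthetic: dict | None = None
    measurements: dict | None = None  # {"WT": {"rep1": [csv, ...]}, "G31C": ...}
    map_path: str | None = None
    curves_path: str | None = None

    def __post_init__(self) -> None:
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def plate_spec(self) -> PlateSpec:
        return PlateSpec(**self.spec)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, str(e)) from e
        return wrapped
    return deco


def _synthetic_measurements(config: RunConfig, spec: PlateSpec):
    """Generate the synthetic screen: plate map, truth, measurement tables."""
    syn = dict(config.synthetic or {})
    n_strains = syn.get("n_strains", 3800)
    n_dup = syn.get("n_duplicates", 402)
    n_plates = syn.get("n_plates", 3)
    n_reps = syn.get("n_replicates", 3)
    render = syn.get("render_images", False)
    truth_kwargs = syn.get("truth", {})

    pmap = generate_plate_map(spec, n_strains, n_dup, n_plates=n_plates,
                              seed=config.seed)
    strains = sorted(set(pmap["strain_id"]) - {"EMPTY"})
    truth = default_screen_truth(strains, seed=config.seed, **truth_kwargs)

    measurements = {"WT": {}, "G31C": {}}
    for reporter in ("WT", "G31C"):
        for r in range(1, n_reps + 1):
            rep = f"rep{r}"
            if render:
                pairs, _ = simulate_colony_plates(
                    pmap, spec, truth, reporter, config.timepoint, rep
                )
                tables = [
                    quantify_plate(p, pmap, spec,
                                   low_growth_floor=config.growth_floor)
                    for p in pairs
                ]
                table = pd.concat(tables, ignore_index=True)
            else:
                table = simulate_screen_tables(
                    pmap, spec, truth, reporter, config.timepoint, rep
                )
            measurements[reporter][rep] = table
    return pmap, truth, measurements


@_stage("quantify")
def _load_measurements(config: RunConfig, spec: PlateSpec):
    if config.synthetic is not None:
        return _synthetic_measurements(config, spec)
    if not config.measurements:
        raise ValueError("config provides neither synthetic nor measurements")
    pmap = rio.read_plate_map(config.map_path) if config.map_path else None
    out = {}
    for reporter, reps in config.measurements.items():
        out[reporter] = {
            rep: pd.concat([pd.read_csv(p) for p in paths], ignore_index=True)
            for rep, paths in reps.items()
        }
    if "WT" not in out:
        raise ValueError("no WT measurement tables configured")
    return pmap, None, out


def run_screen(config: RunConfig) -> dict:
    """Execute the full screen pipeline; returns the result bundle.

    The bundle holds the normalized record tables, the expression index, hit
    lists, QC and concordance summaries, and the paths of everything written
    under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.plate_spec()

    pmap, truth, measurements = _load_measurements(config, spec)
    if "G31C" not in measurements or not measurements["G31C"]:
        raise StageError("control_normalize", "no G31C control measurements")

    normalized = {}
    for reporter, reps in measurements.items():
        normalized[reporter] = {}
        for rep, table in reps.items():
            log.info("normalizing %s %s (%d colonies)", reporter, rep, len(table))
            rec = _stage("compute_ratio")(compute_ratio)(
                table, config.growth_floor
            )
            rec = _stage("spatial_normalize")(spatial_normalize)(
                rec, spec, config.smooth_window
            )
            normalized[reporter][rep] = rec

    per_strain = {
        reporter: _stage("combine_replicates")(combine_replicates)(
            list(reps.values())
        )
        for reporter, reps in normalized.items()
    }
    index = _stage("control_normalize")(control_normalize)(
        per_strain["WT"], per_strain["G31C"]
    )
    hits = _stage("call_hits")(call_hits)(index, config.threshold_k)

    qc = {}
    for reporter, reps in normalized.items():
        for rep, rec in reps.items():
            qc[f"{reporter}_{rep}"] = _stage("plate_qc")(plate_qc)(rec, spec)
    if len(normalized["WT"]) >= 2:
        pearson = _stage("replicate_pearson")(replicate_pearson)(
            list(normalized["WT"].values())
        )
    else:
        log.warning("single replicate: skipping Pearson reproducibility check")
        pearson = pd.DataFrame()
    concordance = (None, None)
    if pmap is not None:
        concordance = _stage("duplicate_concordance")(duplicate_concordance)(
            list(normalized["WT"].values()), pmap
        )

    files = []
    wt_records = pd.concat(normalized["WT"].values(), ignore_index=True)
    for name, df in [
        ("index.csv", index),
        ("per_strain_wt.csv", per_strain["WT"]),
        ("per_strain_g31c.csv", per_strain["G31C"]),
        ("pearson.csv", pearson),
    ]:
        path = outdir / name
        df.to_csv(path, index=(name == "pearson.csv"))
        files.append(path)
    if concordance[0] is not None:
        path = outdir / "duplicates.csv"
        concordance[0].to_csv(path, index=False)
        files.append(path)
    rendered = _stage("render_outputs")(render_outputs)(
        index, hits, wt_records, outdir, config.threshold_k
    )
    files.extend(rendered.values())
    import json

    path = outdir / "qc.json"
    qc_payload = {"plates": qc}
    if concordance[1] is not None:
        qc_payload["duplicates"] = concordance[1]
    with open(path, "w") as fh:
        json.dump(qc_payload, fh, indent=2, sort_keys=True)
    files.append(path)

    params = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    manifest = rio.write_manifest(outdir, params, files)
    return {
        "normalized": normalized,
        "per_strain": per_strain,
        "index": index,
        "hits": hits,
        "qc": qc_payload,
        "pearson": pearson,
        "truth": truth,
        "plate_map": pmap,
        "files": files + [manifest],
        "outdir": outdir,
    }


def run_kinetics(config: RunConfig) -> dict:
    """Execute the kinetics pipeline: blanks -> F/OD -> phases -> regulation."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.curves_path:
        curves = rio.read_curves(config.curves_path)
    elif config.synthetic is not None:
        syn = dict(config.synthetic)
        truth = KineticsTruth(seed=config.seed, **syn.get("truth", {}))
        concs = syn.get(
            "tpp_concs", [0.0, 5e-8, 1e-7, 2.5e-7, 1e-6, 1e-4, 1e-3]
        )
        curves = simulate_growth_curves(
            truth, concs,
            t_end=syn.get("t_end", 16.0),
            dt=syn.get("dt", 1.0 / 6.0),
            n_wells=syn.get("n_wells", 3),
        )
    else:
        raise StageError("input", "config provides neither curves nor synthetic")

    corrected = _stage("blank_correct")(kin.blank_correct)(curves)

    rows = []
    for (well, conc), g in corrected.groupby(["well", "condition_molar"]):
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy()
        od = g["od600"].to_numpy()
        ratio = kin.ratio_curve(t, od, g["fluorescence"].to_numpy())
        mid = _stage("exponential_midpoint")(kin.exponential_midpoint)(t, od)
        expo, stat = _stage("phase_values")(kin.phase_values)(
            t, ratio, mid, config.stationary_t
        )
        rows.append((well, conc, mid, expo, stat))
    wells = pd.DataFrame(
        rows, columns=["well", "condition_molar", "midpoint_h",
                       "exponential", "stationary"]
    )
    per_cond = wells.groupby("condition_molar")[["exponential", "stationary"]] \
        .mean().reset_index()
    values = per_cond.melt(
        id_vars="condition_molar", value_vars=["exponential", "stationary"],
        var_name="phase", value_name="f_over_od",
    )
    values["phase"] = values["phase"].str.upper()
    regulation = _stage("fold_regulation")(kin.fold_regulation)(
        values, config.reference_molar
    )
    dr_table, dr_summary = _stage("dose_response")(kin.dose_response)(regulation)

    files = []
    for name, df in [
        ("curves_corrected.csv", corrected),
        ("phase_values.csv", wells),
        ("regulation.csv", regulation),
        ("dose_response.csv", dr_table),
    ]:
        path = outdir / name
        df.to_csv(path, index=False)
        files.append(path)
    import json

    path = outdir / "dose_response_summary.json"
    with open(path, "w") as fh:
        json.dump(dr_summary, fh, indent=2, sort_keys=True)
    files.append(path)
    params = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    manifest = rio.write_manifest(outdir, params, files)
    return {
        "curves": corrected,
        "wells": wells,
        "regulation": regulation,
        "dose_response": dr_table,
        "dose_response_summary": dr_summary,
        "files": files + [manifest],
        "outdir": outdir,
    }
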