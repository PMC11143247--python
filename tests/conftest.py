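import numpy as np
import pandas as pd
import pytest

import riboscreen as rs


@pytest.fixture(scope="session")
def spec():
    return rs.PlateSpec()


@pytest.fixture(scope="session")
def small_screen(spec):
    """One rendered 1536 plate (1200 strains, 100 duplicated) plus truth."""
    pmap = rs.generate_plate_map(spec, 1200, 100, seed=11)
    strains = sorted(set(pmap["strain_id"]) - {rs.EMPTY})
    truth = rs.default_screen_truth(strains, seed=11, n_high=7, n_low=2,
                                    n_artifact=3)
    pairs, tdf = rs.simulate_colony_plates(pmap, spec, truth, "WT", "24h",
                                           "rep1")
    return {"map": pmap, "truth": truth, "pair": pairs[0], "planted": tdf}


@pytest.fixture(scope="session")
def quantified(small_screen, spec):
    table = rs.quantify_plate(small_screen["pair"], small_screen["map"], spec)
    return table.merge(
        small_screen["planted"][["plate_id", "row", "col",
                                 "planted_biomass", "planted_fluor",
                                 "planted_ratio"]],
        on=["plate_id", "row", "col"],
    )


def gradient_only_truth(strains, amplitude=1.5, noise_cv=0.10, seed=0,
                        **kwargs):
    """Truth with a planted border gradient but no hits/artifacts/baselines."""
    return rs.ScreenTruth(
        strain_baseline={s: 1.0 for s in strains},
        edge_amplitude=amplitude,
        noise_cv=noise_cv,
        seed=seed,
        **kwargs,
    )


def edge_distance(df, spec):
    r = df["row"].to_numpy()
    c = df["col"].to_numpy()
    return np.minimum.reduce([r - 1, c - 1, spec.n_rows - r, spec.n_cols - c])


def run_fast_screen(seed, n_strains=3800, n_duplicates=402, n_plates=3,
                    n_reps=3, threshold_k=5.0, truth_kwargs=None):
    """Measurement-level screen: map -> truth -> normalize -> index -> hits."""
    spec = rs.PlateSpec()
    pmap = rs.generate_plate_map(spec, n_strains, n_duplicates,
                                 n_plates=n_plates, seed=seed)
    strains = sorted(set(pmap["strain_id"]) - {rs.EMPTY})
    truth = rs.default_screen_truth(strains, seed=seed, **(truth_kwargs or {}))
    per = {}
    normalized = {}
    for reporter in ("WT", "G31C"):
        tables = []
        for r in range(1, n_reps + 1):
            t = rs.simulate_screen_tables(pmap, spec, truth, reporter, "24h",
                                          f"rep{r}")
            tables.append(rs.spatial_normalize(rs.compute_ratio(t), spec))
        normalized[reporter] = tables
        per[reporter] = rs.combine_replicates(tables)
    index = rs.control_normalize(per["WT"], per["G31C"])
    hits = rs.call_hits(index, threshold_k)
    return {
        "spec": spec, "map": pmap, "truth": truth, "normalized": normalized,
        "per_strain": per, "index": index, "hits": hits,
    }
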