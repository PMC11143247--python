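"""Plate-reader reporter kinetics: blank correction, F/OD, phases, regulation.

Analyses long-format growth/fluorescence time series into the standard
reporter summaries: blank-corrected curves, pointwise fluorescence/OD600,
growth-phase readouts (exponential = half-amplitude midpoint of the OD curve,
stationary = 16 h), ligand-normalized expression and fold regulation, and
dose-response summaries over a titration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MissingBlankError",
    "PhaseDetectionError",
    "blank_correct",
    "ratio_curve",
    "exponential_midpoint",
    "phase_values",
    "fold_regulation",
    "dose_response",
]

EXPONENTIAL = "EXPONENTIAL"
STATIONARY = "STATIONARY"


class MissingBlankError(ValueError):
    """No blank wells available for correction."""


class PhaseDetectionError(RuntimeError):
    """Growth curve never reaches a usable plateau."""


def blank_correct(curves: pd.DataFrame) -> pd.DataFrame:
    """Subtract the time-matched median blank from every sample well.

    Blank wells (``is_blank``) provide the medium OD and autofluorescence
    offsets per time point; corrected readings are clipped at zero and blank
    wells are dropped from the output.
    """
    blanks = curves[curves["is_blank"]]
    if blanks.empty:
        raise MissingBlankError("no blank wells in input")
    med = blanks.groupby("time_h")[["od600", "fluorescence"]].median()
    out = curves[~curves["is_blank"]].copy()
    out["od600"] = np.clip(
        out["od600"] - med["od600"].reindex(out["time_h"]).to_numpy(), 0, None
    )
    out["fluorescence"] = np.clip(
        out["fluorescence"] - med["fluorescence"].reindex(out["time_h"]).to_numpy(),
        0, None,
    )
    return out


def ratio_curve(
    time_h: np.ndarray,
    od600: np.ndarray,
    fluor: np.ndarray,
    od_floor: float = 0.02,
) -> np.ndarray:
    """Pointwise fluorescence/OD; undefined (NaN) where OD < ``od_floor``.

    The floor avoids blank-noise blowup before growth is measurable.
    """
    od = np.asarray(od600, dtype=float)
    fl = np.asarray(fluor, dtype=float)
    ratio = np.full_like(od, np.nan)
    ok = od >= od_floor
    ratio[ok] = fl[ok] / od[ok]
    return ratio


def exponential_midpoint(time_h: np.ndarray, od600: np.ndarray) -> float:
    """Time of the half-amplitude OD crossing ("midpoint of maximal amplitude").

    Returns the first time at which the blank-corrected OD crosses
    ``(OD_min + OD_max) / 2``, linearly interpolated between samples; for a
    symmetric logistic this is the inflection time. Raises
    ``PhaseDetectionError`` if the amplitude never clearly exceeds the noise.
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if t.size < 3:
        raise PhaseDetectionError("too few samples")
    noise = 1.4826 * np.median(np.abs(np.diff(od))) / np.sqrt(2) + 1e-12
    amp = od.max() - od.min()
    if amp <= 8 * noise:
        raise PhaseDetectionError(
            f"OD amplitude {amp:.4f} not above noise scale {noise:.4f}"
        )
    target = (od.min() + od.max()) / 2.0
    above = od >= target
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1, v0, v1 = t[i - 1], t[i], od[i - 1], od[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (target - v0) / (v1 - v0) * (t1 - t0))


def phase_values(
    time_h: np.ndarray,
    ratio: np.ndarray,
    midpoint_h: float,
    stationary_t: float = 16.0,
) -> tuple[float, float]:
    """F/OD interpolated at the exponential midpoint and at stationary phase."""
    t = np.asarray(time_h, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if t.max() < stationary_t:
        raise ValueError(
            f"series ends at {t.max():.2f} h, before stationary readout at "
            f"{stationary_t:.2f} h"
        )
    ok = np.isfinite(r)
    if not ok.any():
        raise ValueError("ratio series has no defined points")
    tv, rv = t[ok], r[ok]
    if midpoint_h < tv[0] or midpoint_h > tv[-1]:
        raise ValueError(
            f"midpoint {midpoint_h:.2f} h outside the defined ratio range "
            f"[{tv[0]:.2f}, {tv[-1]:.2f}]"
        )
    return float(np.interp(midpoint_h, tv, rv)), float(np.interp(stationary_t, tv, rv))


def fold_regulation(
    values: pd.DataFrame,
    reference_molar: float = 0.0,
) -> pd.DataFrame:
    """Normalize phase values to the no-ligand reference condition.

    ``values`` has columns ``condition_molar, phase, f_over_od`` (one row per
    condition and phase). The reference condition maps to
    ``normalized_expression`` exactly 1; ``fold_regulation`` is its reciprocal
    (larger = stronger repression).
    """
    out = values.copy()
    out["normalized_expression"] = np.nan
    out["fold_regulation"] = np.nan
    for phase, idx in out.groupby("phase").groups.items():
        sub = out.loc[idx]
        ref = sub[sub["condition_molar"] == reference_molar]
        if ref.empty:
            raise ValueError(f"no reference condition ({reference_molar} M) "
                             f"for phase {phase}")
        ref_v = float(ref["f_over_od"].iloc[0])
        if ref_v == 0:
            raise ValueError(f"reference F/OD is zero in phase {phase}")
        out.loc[idx, "normalized_expression"] = sub["f_over_od"] / ref_v
        out.loc[idx, "fold_regulation"] = ref_v / sub["f_over_od"]
    return out


def dose_response(results: pd.DataFrame, phase: str = STATIONARY):
    """Dose-response summary over a titration at one growth phase.

    Returns ``(table, summary)`` where the table is normalized expression vs
    concentration (ascending) and the summary reports the maximal fractional
    repression, the lowest concentration reaching >= 90% of it, an
    interpolated half-repression concentration, and the count of isotonic
    violations (adjacent concentration steps where expression increases).
    A flat response yields undefined (None) saturation/half-repression.
    """
    sub = results[results["phase"] == phase].copy()
    sub = sub.sort_values("condition_molar").reset_index(drop=True)
    if sub["condition_molar"].nunique() < 3:
        raise ValueError("need >= 3 concentrations for a dose-response")
    conc = sub["condition_molar"].to_numpy(dtype=float)
    norm = sub["normalized_expression"].to_numpy(dtype=float)

    max_repression = float(1.0 - np.nanmin(norm))
    viol = int(np.sum(np.diff(norm) > 1e-9))
    summary = {
        "max_repression": max_repression,
        "isotonic_violations": viol,
        "saturating_conc_molar": None,
        "half_repression_conc_molar": None,
    }
    if max_repression > 0.05:
        repr_frac = (1.0 - norm) / max_repression
        reached = conc[(repr_frac >= 0.9) & (conc > 0)]
        if reached.size:
            summary["saturating_conc_molar"] = float(reached.min())
        pos = conc > 0
        cpos, rpos = conc[pos], repr_frac[pos]
        cross = np.nonzero((rpos[:-1] < 0.5) & (rpos[1:] >= 0.5))[0]
        if rpos.size and rpos[0] >= 0.5:
            summary["half_repression_conc_molar"] = float(cpos[0])
        elif cross.size:
            i = int(cross[0])
            lc = np.log10(cpos)
            f = (0.5 - rpos[i]) / (rpos[i + 1] - rpos[i])
            summary["half_repression_conc_molar"] = float(
                10 ** (lc[i] + f * (lc[i + 1] - lc[i]))
            )
    return sub, summary
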