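"""Per-plate fluorescence/biomass ratios and spatial (border-effect) correction.

The screen's base observable is the per-colony integrated fluorescence divided
by integrated biomass. Plates carry smooth multiplicative spatial trends
(border/incubator effects); these are estimated per plate with a robust local
trend over the grid and divided out, then the plate is rescaled to median 1 so
strains are comparable across plates and replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .simulate import EMPTY, PlateSpec

__all__ = [
    "EmptyPlateError",
    "compute_ratio",
    "spatial_normalize",
    "plate_qc",
]


class EmptyPlateError(ValueError):
    """Every colony on a plate was excluded."""


def compute_ratio(
    measurements: pd.DataFrame,
    growth_floor: float = 0.1,
) -> pd.DataFrame:
    """Fluorescence/biomass ratio per colony, excluding empty and failed pins.

    A colony is excluded (``ratio`` undefined, never zero) when its position is
    EMPTY or its biomass falls below ``growth_floor`` times the plate median of
    non-empty biomass. Exclusions carry reasons and propagate as missing
    values downstream.
    """
    out = measurements.copy()
    out["excluded"] = False
    out["exclude_reason"] = ""
    out["ratio"] = np.nan

    for _, idx in out.groupby("plate_id").groups.items():
        sub = out.loc[idx]
        occupied = sub["strain_id"] != EMPTY
        med = sub.loc[occupied, "biomass_sum"].median()
        empty = ~occupied
        low = occupied & (sub["biomass_sum"] < growth_floor * med)
        ok = occupied & ~low
        out.loc[idx[empty], ["excluded", "exclude_reason"]] = [True, "EMPTY"]
        out.loc[idx[low], ["excluded", "exclude_reason"]] = [True, "LOW_GROWTH"]
        out.loc[idx[ok], "ratio"] = (
            sub.loc[ok, "fluor_sum"] / sub.loc[ok, "biomass_sum"]
        )
        if not ok.any():
            raise EmptyPlateError(
                f"all colonies excluded on plate {sub['plate_id'].iloc[0]}"
            )
    return out


def _robust_local_surface(grid: np.ndarray, window: int, n_iter: int = 3) -> np.ndarray:
    """Robust local-quadratic trend of a 2D grid with missing values.

    For every cell, fits a 2D quadratic by iteratively trimmed weighted least
    squares over a ``window x window`` neighbourhood (clipped at the grid
    edge). A local quadratic tracks the curvature of border/incubator trends
    without the boundary bias a running median or local-linear fit would show
    on monotone edge gradients. Isolated outliers are down-weighted with
    bisquare weights (lowess-style), so single-colony hits survive the
    correction instead of being absorbed into the trend.
    """
    h = window // 2
    R, C = grid.shape
    padded = np.full((R + 2 * h, C + 2 * h), np.nan)
    padded[h:-h, h:-h] = grid
    win = sliding_window_view(padded, (window, window)).reshape(R, C, -1)

    off = np.arange(-h, h + 1, dtype=float)
    dy = np.repeat(off, window)
    dx = np.tile(off, window)
    X = np.stack([np.ones_like(dy), dy, dx, dy * dy, dy * dx, dx * dx],
                 axis=1)  # (w^2, 6)
    p = X.shape[1]

    vals = np.where(np.isfinite(win), win, 0.0)
    finite = np.isfinite(win)
    W = finite.astype(float)
    level = np.abs(np.nanmedian(win, axis=-1, keepdims=True)) + 1e-12
    surface = None
    for _ in range(n_iter):
        A = np.einsum("rck,ki,kj->rcij", W, X, X)
        b = np.einsum("rck,rck,ki->rci", W, vals, X)
        A = A + 1e-9 * np.eye(p)
        coef = np.linalg.solve(A, b[..., None])[..., 0]
        surface = coef[..., 0]
        resid = win - np.einsum("rci,ki->rck", coef, X)
        resid = np.where(finite, resid, np.nan)
        mad = np.nanmedian(np.abs(resid), axis=-1, keepdims=True)
        # soft bisquare robustification; the floor (1% of the local level)
        # keeps near-noise-free fits from treating their own structure as
        # outliers
        scale = np.maximum(1.4826 * mad, 0.01 * level) + 1e-12
        u = np.nan_to_num(resid, nan=np.inf) / (6.0 * scale)
        W = np.where(finite & (np.abs(u) < 1), (1 - u**2) ** 2, 0.0)
        # never fit on fewer points than the model has parameters
        thin = (W > 0).sum(axis=-1) < p + 1
        if thin.any():
            W[thin] = finite[thin].astype(float)

    few = finite.sum(axis=-1) < p + 1
    if few.any():
        surface[few] = np.nanmedian(win[few], axis=-1)
    return surface


def _ring_factors(grid: np.ndarray, depth: int) -> np.ndarray:
    """Per-cell multiplicative edge-ring factor (Chebyshev distance rings).

    Border effects on pinned arrays are ring-structured (each ring of cells
    at the same distance from the nearest plate edge shares nutrient and
    incubator exposure), so each of the ``depth`` outer rings is rescaled by
    the ratio of its median to the interior median. Cells deeper than
    ``depth`` get factor 1.
    """
    R, C = grid.shape
    rr = np.arange(R)[:, None]
    cc = np.arange(C)[None, :]
    d = np.minimum(np.minimum(rr, R - 1 - rr), np.minimum(cc, C - 1 - cc))
    factors = np.ones((R, C))
    interior = d >= depth
    if not np.isfinite(grid[interior]).any():
        return factors
    ref = np.nanmedian(grid[interior])
    if not ref > 0:
        return factors
    for k in range(depth):
        ring = d == k
        med = np.nanmedian(grid[ring]) if np.isfinite(grid[ring]).any() else ref
        if med > 0:
            factors[ring] = med / ref
    return factors


def spatial_normalize(
    records: pd.DataFrame,
    spec: PlateSpec | None = None,
    smooth_window: int = 13,
    edge_depth: int = 4,
) -> pd.DataFrame:
    """Divide out the per-plate spatial trend and rescale the plate median to 1.

    ``ratio_corrected = ratio / local_surface(row, col)``. The local surface
    is the product of a robust edge-ring correction (median of each of the
    ``edge_depth`` outer Chebyshev rings relative to the plate interior — the
    border effect proper) and a robust local-quadratic trend over the
    ring-corrected grid (incubator gradients and other smooth fields). Each
    plate is then rescaled so the median corrected ratio over included
    colonies is exactly 1. Single-colony outliers survive: both stages are
    median/bisquare-robust.
    """
    if smooth_window < 3 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 3")
    out = records.copy()
    out["ratio_corrected"] = np.nan
    for plate_id, idx in out.groupby("plate_id").groups.items():
        sub = out.loc[idx]
        n_rows = spec.n_rows if spec is not None else int(sub["row"].max())
        n_cols = spec.n_cols if spec is not None else int(sub["col"].max())
        grid = np.full((n_rows, n_cols), np.nan)
        r = sub["row"].to_numpy() - 1
        c = sub["col"].to_numpy() - 1
        ratio = sub["ratio"].to_numpy()
        grid[r, c] = ratio
        rings = _ring_factors(grid, edge_depth)
        surface = rings * _robust_local_surface(grid / rings, smooth_window)
        corr = ratio / surface[r, c]
        med = np.nanmedian(corr)
        if not np.isfinite(med) or med <= 0:
            raise EmptyPlateError(f"no usable ratios on plate {plate_id}")
        out.loc[idx, "ratio_corrected"] = corr / med
    return out


def _edge_distance(records: pd.DataFrame, spec: PlateSpec) -> np.ndarray:
    r = records["row"].to_numpy()
    c = records["col"].to_numpy()
    return np.minimum.reduce([r - 1, c - 1, spec.n_rows - r, spec.n_cols - c])


def plate_qc(records: pd.DataFrame, spec: PlateSpec | None = None) -> dict:
    """Per-plate QC summary: exclusions, medians, border-vs-center ratios."""
    if records.empty:
        raise EmptyPlateError("no records to QC")
    report = {}
    for plate_id, sub in records.groupby("plate_id"):
        n_rows = spec.n_rows if spec is not None else int(sub["row"].max())
        n_cols = spec.n_cols if spec is not None else int(sub["col"].max())
        local_spec_d = np.minimum.reduce([
            sub["row"].to_numpy() - 1,
            sub["col"].to_numpy() - 1,
            n_rows - sub["row"].to_numpy(),
            n_cols - sub["col"].to_numpy(),
        ])
        border = local_spec_d == 0
        center = local_spec_d >= 4
        inc = ~sub["excluded"].to_numpy()

        def _med(col, mask):
            v = sub.loc[mask & inc, col]
            return float(v.median()) if len(v) else float("nan")

        entry = {
            "n_total": int(len(sub)),
            "n_included": int(inc.sum()),
            "n_excluded": int((~inc).sum()),
            "n_empty": int((sub["exclude_reason"] == "EMPTY").sum()),
            "n_low_growth": int((sub["exclude_reason"] == "LOW_GROWTH").sum()),
            "n_saturated": int(sub["flags"].str.contains("SATURATED").sum())
            if "flags" in sub else 0,
            "median_ratio": _med("ratio", np.ones(len(sub), dtype=bool)),
            "border_center_ratio_raw": _med("ratio", border) / _med("ratio", center),
        }
        if "ratio_corrected" in sub:
            entry["border_center_ratio_corrected"] = (
                _med("ratio_corrected", border) / _med("ratio_corrected", center)
            )
        report[str(plate_id)] = entry
    return report
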