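"""Colony-array image quantification.

Converts a registered white-light / fluorescence image pair plus a plate map
into per-colony integrated intensities: background removal, rigid-grid ROI
placement, and pixel-sum extraction (integrated intensity — the sum of pixel
values, never a mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .simulate import EMPTY, PlateImagePair, PlateSpec

__all__ = [
    "GridDetectionError",
    "GridGeometry",
    "estimate_background",
    "subtract_background",
    "detect_grid",
    "measure_colony",
    "quantify_plate",
]


class GridDetectionError(RuntimeError):
    """Raised when too few colony peaks support the fitted grid."""


@dataclass
class GridGeometry:
    """Rigid-grid fit: per-axis origin (first node) and pitch, plus all nodes."""

    origin_yx: tuple[float, float]
    pitch_yx: tuple[float, float]
    n_rows: int
    n_cols: int
    found_fraction: float

    @property
    def nodes(self) -> np.ndarray:
        """(n_rows, n_cols, 2) array of node pixel coordinates (y, x)."""
        ys = self.origin_yx[0] + np.arange(self.n_rows) * self.pitch_yx[0]
        xs = self.origin_yx[1] + np.arange(self.n_cols) * self.pitch_yx[1]
        return np.stack(np.meshgrid(ys, xs, indexing="ij"), axis=-1)


def estimate_background(image: np.ndarray, window: int,
                        percentile: float = 10.0) -> np.ndarray:
    """Smooth background surface via a large-window lower-envelope filter.

    Computes a running low percentile (default 10th — a rolling-ball-like
    lower envelope, far less sensitive than a median to the Gaussian tails of
    colony foreground) on a strided subsample of the image and interpolates
    back to full resolution, which keeps the large window tractable on full
    1536-array images. ``window`` should be at least ~3x the expected colony
    diameter so colonies stay a minority inside every window.
    """
    image = np.asarray(image, dtype=float)
    if window > min(image.shape):
        raise ValueError(
            f"window {window} exceeds image extent {min(image.shape)}"
        )
    if window < 3:
        raise ValueError("window must be >= 3 pixels")
    stride = max(1, window // 10)
    small = image[::stride, ::stride]
    w = max(3, int(round(window / stride)) | 1)
    bg_small = ndimage.percentile_filter(small, percentile, size=w,
                                         mode="nearest")
    if stride == 1:
        return bg_small
    ys = np.arange(0, image.shape[0], stride)
    xs = np.arange(0, image.shape[1], stride)
    interp = RegularGridInterpolator(
        (ys, xs), bg_small, bounds_error=False, fill_value=None
    )
    yy, xx = np.meshgrid(
        np.arange(image.shape[0]), np.arange(image.shape[1]), indexing="ij"
    )
    return interp(np.stack([yy.ravel(), xx.ravel()], axis=-1)).reshape(image.shape)


def subtract_background(image: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Elementwise ``max(image - background, 0)``."""
    image = np.asarray(image, dtype=float)
    background = np.asarray(background, dtype=float)
    if image.shape != background.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs background {background.shape}"
        )
    return np.clip(image - background, 0.0, None)


def _fit_axis(profile: np.ndarray, n_nodes: int, pitch0: float, origin0: float):
    """Best (origin, pitch) for one axis by maximizing summed profile at nodes."""
    pos = np.arange(profile.size, dtype=float)

    def score(origin, pitch):
        nodes = origin + pitch * np.arange(n_nodes)
        return np.interp(nodes, pos, profile, left=0.0, right=0.0).sum()

    best = (origin0, pitch0, -np.inf)
    for pitch in np.arange(pitch0 - 0.5, pitch0 + 0.5001, 0.05):
        for origin in np.arange(origin0 - 0.6 * pitch0, origin0 + 0.6 * pitch0, 0.25):
            s = score(origin, pitch)
            if s > best[2]:
                best = (origin, pitch, s)
    o0, p0, _ = best
    for pitch in np.arange(p0 - 0.06, p0 + 0.0601, 0.01):
        for origin in np.arange(o0 - 0.3, o0 + 0.3001, 0.05):
            s = score(origin, pitch)
            if s > best[2]:
                best = (origin, pitch, s)
    return best[0], best[1]


def detect_grid(
    image: np.ndarray,
    spec: PlateSpec,
    background: np.ndarray | None = None,
    min_found: float = 0.25,
) -> GridGeometry:
    """Fit a rigid fixed-pitch grid to a plate image.

    Seeds from the configured geometry and maximizes the summed
    background-subtracted row/column projection profiles at the node
    positions, searching origin (±0.6 pitch) and pitch (±0.5 px) per axis.
    Pinned arrays are rigid, so no per-colony segmentation is attempted.
    """
    img = np.asarray(image, dtype=float)
    if background is None:
        background = estimate_background(img, int(2 * spec.pitch_px) | 1)
    fg = subtract_background(img, background)

    oy, py = _fit_axis(fg.sum(axis=1), spec.n_rows, spec.pitch_px, spec.margin_px)
    ox, px = _fit_axis(fg.sum(axis=0), spec.n_cols, spec.pitch_px, spec.margin_px)
    geom = GridGeometry((oy, ox), (py, px), spec.n_rows, spec.n_cols, 0.0)

    # peak support: a node counts as found if a local max near it clearly
    # exceeds the residual noise floor
    noise = 1.4826 * np.median(np.abs(fg)) + 1e-9
    peaks = ndimage.maximum_filter(fg, size=5)
    nodes = geom.nodes.reshape(-1, 2)
    iy = np.clip(np.round(nodes[:, 0]).astype(int), 0, fg.shape[0] - 1)
    ix = np.clip(np.round(nodes[:, 1]).astype(int), 0, fg.shape[1] - 1)
    found = peaks[iy, ix] > 6 * noise
    frac = float(found.mean())
    geom.found_fraction = frac
    if frac < min_found:
        raise GridDetectionError(
            f"only {found.sum()} of {found.size} expected colony peaks "
            f"({frac:.0%}) support the fitted grid "
            f"(origin={geom.origin_yx}, pitch={geom.pitch_yx})"
        )
    return geom


def measure_colony(
    image: np.ndarray,
    node_yx: tuple[float, float],
    roi_half_side: float,
) -> tuple[float, int, bool]:
    """Integrated intensity (pixel SUM, not mean) in a square ROI at a node.

    Returns ``(total, roi_area_px, clipped)`` where ``clipped`` marks ROIs
    truncated by the image edge.
    """
    image = np.asarray(image)
    cy, cx = node_yx
    half = int(round(roi_half_side))
    y0, y1 = int(round(cy)) - half, int(round(cy)) + half + 1
    x0, x1 = int(round(cx)) - half, int(round(cx)) + half + 1
    clipped = y0 < 0 or x0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]
    y0c, x0c = max(y0, 0), max(x0, 0)
    y1c, x1c = min(y1, image.shape[0]), min(x1, image.shape[1])
    roi = image[y0c:y1c, x0c:x1c]
    return float(roi.sum(dtype=float)), int(roi.size), bool(clipped)


def quantify_plate(
    pair: PlateImagePair,
    plate_map: pd.DataFrame,
    spec: PlateSpec,
    background_window: int | None = None,
    roi_frac: float = 0.8,
    low_growth_floor: float = 0.1,
    saturation_frac: float = 0.05,
) -> pd.DataFrame:
    """Quantify one plate image pair into a per-colony measurement table.

    Background is estimated and subtracted independently per channel; the grid
    is fitted on the white-light image and the same ROIs are applied to both
    channels (the images are acquired registered). The square ROI side is
    ``roi_frac`` of the pitch, so neighbouring ROIs never overlap.
    """
    pmap = plate_map[plate_map["plate_id"] == pair.plate_id] \
        if "plate_id" in plate_map and plate_map["plate_id"].nunique() > 1 \
        else plate_map
    if len(pmap) != spec.density:
        raise ValueError(
            f"plate map for {pair.plate_id} has {len(pmap)} entries, "
            f"expected {spec.density}"
        )
    if background_window is None:
        background_window = int(2 * spec.pitch_px) | 1

    vmax = 2**spec.bit_depth - 1
    bio = np.asarray(pair.biomass_image, dtype=float)
    flu = np.asarray(pair.fluor_image, dtype=float)
    bio_fg = subtract_background(bio, estimate_background(bio, background_window))
    flu_fg = subtract_background(flu, estimate_background(flu, background_window))
    geom = detect_grid(bio, spec, background=None)
    nodes = geom.nodes
    half = roi_frac * min(geom.pitch_yx) / 2

    rows = []
    for rec in pmap.itertuples(index=False):
        node = tuple(nodes[rec.row - 1, rec.col - 1])
        b_sum, area, clip_b = measure_colony(bio_fg, node, half)
        f_sum, _, _ = measure_colony(flu_fg, node, half)
        sat_b, n_roi, _ = measure_colony(
            (np.asarray(pair.biomass_image) >= vmax).astype(float), node, half
        )
        sat_f, _, _ = measure_colony(
            (np.asarray(pair.fluor_image) >= vmax).astype(float), node, half
        )
        flags = []
        if rec.strain_id == EMPTY:
            flags.append("EMPTY")
        if clip_b:
            flags.append("EDGE_OF_IMAGE")
        if max(sat_b, sat_f) / max(n_roi, 1) > saturation_frac:
            flags.append("SATURATED")
        rows.append(
            (pair.plate_id, pair.replicate_id, pair.timepoint, pair.reporter,
             rec.row, rec.col, rec.strain_id, b_sum, f_sum, area,
             "|".join(flags))
        )
    out = pd.DataFrame(
        rows,
        columns=["plate_id", "replicate_id", "timepoint", "reporter", "row",
                 "col", "strain_id", "biomass_sum", "fluor_sum", "roi_area",
                 "flags"],
    )
    occupied = out["strain_id"] != EMPTY
    med = out.loc[occupied, "biomass_sum"].median()
    low = occupied & (out["biomass_sum"] < low_growth_floor * med)
    out.loc[low, "flags"] = np.where(
        out.loc[low, "flags"] == "", "LOW_GROWTH",
        out.loc[low, "flags"] + "|LOW_GROWTH",
    )
    return out
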