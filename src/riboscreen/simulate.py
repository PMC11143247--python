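"""Synthetic colony-array screens and plate-reader kinetics with planted truth.

This module emulates a Keio-style 1536-density reporter screen: pinned colony
grids imaged in white light (biomass) and fluorescence, a multiplicative
border/incubator gradient, strain-specific riboswitch effects applied only to
the functional (WT) reporter, artifact effects applied to both WT and the
binding-dead control reporter, duplicated strains, and logistic growth curves
with Hill-type ligand-dependent reporter repression (the thiC riboswitch is an
OFF switch: ligand represses the reporter).

Everything is driven by explicit truth objects so that every downstream stage
(quantification, spatial normalization, index construction, hit calling,
kinetics summaries) can be checked against planted expectations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EMPTY = "EMPTY"

__all__ = [
    "EMPTY",
    "PlateSpec",
    "ScreenTruth",
    "KineticsTruth",
    "PlateImagePair",
    "PlateCapacityError",
    "generate_plate_map",
    "default_screen_truth",
    "edge_gradient",
    "plant_colony_truth",
    "simulate_colony_plates",
    "simulate_screen_tables",
    "simulate_growth_curves",
]


class PlateCapacityError(ValueError):
    """Requested strains/duplicates/empties do not fit the plate capacity."""


@dataclass(frozen=True)
class PlateSpec:
    """Geometry of a pinned colony array.

    The default is a 32 x 48 grid (1536 density). ``pitch_px`` is the spacing
    between grid nodes and ``margin_px`` the distance from the image edge to
    the first node; both in pixels of the plate image.
    """

    n_rows: int = 32
    n_cols: int = 48
    pitch_px: float = 20.0
    margin_px: float = 24.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pitch_px < 8:
            raise ValueError("pitch_px must be >= 8")
        if self.margin_px < self.pitch_px / 2:
            raise ValueError("margin_px must be >= pitch_px / 2")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def density(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def image_shape(self) -> tuple[int, int]:
        h = int(round((self.n_rows - 1) * self.pitch_px + 2 * self.margin_px))
        w = int(round((self.n_cols - 1) * self.pitch_px + 2 * self.margin_px))
        return h, w

    def node_yx(self, row: int, col: int) -> tuple[float, float]:
        """Pixel coordinates of a 1-based (row, col) grid node."""
        return (
            self.margin_px + (row - 1) * self.pitch_px,
            self.margin_px + (col - 1) * self.pitch_px,
        )


@dataclass
class ScreenTruth:
    """Planted ground truth of a synthetic colony screen.

    ``riboswitch_effect`` multiplies fluorescence only on WT-reporter plates
    (real TPP-level shifts as reported by the functional riboswitch);
    ``artifact_effect`` multiplies fluorescence on BOTH reporters (e.g. strains
    perturbing plasmid replication); ``strain_baseline`` is continuous
    strain-to-strain expression variation, also shared by both reporters.

    ``edge_amplitude`` is the fluorescence-channel border gradient multiplier
    (the value at the outermost ring, decaying smoothly to 1 over
    ``gradient_decay_cells`` rows/cols inward); ``biomass_edge_amplitude`` is
    the analogous growth gradient. ``noise_cv`` is the lognormal coefficient of
    variation of per-colony totals.
    """

    riboswitch_effect: dict = field(default_factory=dict)
    artifact_effect: dict = field(default_factory=dict)
    strain_baseline: dict = field(default_factory=dict)
    edge_amplitude: float = 1.5
    biomass_edge_amplitude: float = 1.0
    gradient_decay_cells: int = 4
    noise_cv: float = 0.10
    base_biomass: float = 5.0e4
    base_fluor: float = 2.0e4
    growth_scale_4h: float = 0.1
    colony_sigma_px: float = 2.5
    background_level: float = 100.0
    background_tilt: tuple[float, float] = (0.0, 0.0)
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("riboswitch_effect", "artifact_effect", "strain_baseline"):
            bad = [k for k, v in getattr(self, name).items() if not v > 0]
            if bad:
                raise ValueError(f"{name} factors must be > 0 (bad: {bad[:3]})")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.edge_amplitude <= 0 or self.biomass_edge_amplitude <= 0:
            raise ValueError("gradient amplitudes must be > 0")


@dataclass
class KineticsTruth:
    """Planted growth/reporter kinetics: logistic growth plus Hill repression.

    OD follows ``od0 + (K - od0) / (1 + exp(-r (t - t_m)))``. Fluorescence
    accumulates at rate ``alpha * OD(t) * (leak + (1 - leak) * (1 - E_max *
    theta(c)))`` with ``theta(c) = c^n / (K_half^n + c^n)``, so the maximal
    fold repression at saturating ligand is ``1 / (1 - E_max * (1 - leak))``.
    Concentrations are molar; times in hours; fluorescence in arbitrary units.
    """

    od0: float = 0.02
    K: float = 0.8
    r: float = 1.0
    t_m: float = 5.0
    alpha: float = 1500.0
    E_max: float = 0.5
    K_half: float = 1.0e-7
    hill_n: float = 2.0
    leak: float = 0.05
    od_noise_sd: float = 0.003
    fluor_noise_sd: float = 5.0
    blank_od: float = 0.04
    blank_fluor: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.E_max <= 1.0):
            raise ValueError("E_max must lie in [0, 1]")
        if not (self.K > self.od0 > 0):
            raise ValueError("need K > od0 > 0")
        if self.r <= 0:
            raise ValueError("growth rate r must be > 0")
        if self.K_half <= 0:
            raise ValueError("K_half must be > 0")
        if not (0.0 <= self.leak <= 1.0):
            raise ValueError("leak must lie in [0, 1]")


@dataclass
class PlateImagePair:
    """Registered white-light (biomass) and fluorescence images of one plate."""

    biomass_image: np.ndarray
    fluor_image: np.ndarray
    plate_id: str
    replicate_id: str
    timepoint: str
    reporter: str

    def __post_init__(self) -> None:
        if self.biomass_image.shape != self.fluor_image.shape:
            raise ValueError("biomass and fluorescence images must share a shape")


def _subseed(*parts) -> int:
    """Stable 31-bit stream key from arbitrary labels."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def generate_plate_map(
    spec: PlateSpec,
    n_strains: int,
    n_duplicates: int = 0,
    n_empty: int | None = None,
    n_plates: int = 1,
    seed: int = 0,
    strain_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Randomly array strains (some duplicated) over one or more plates.

    Returns a long table with columns ``plate_id, row, col, strain_id`` in
    which every grid position of every plate appears exactly once. Exactly
    ``n_duplicates`` strains occupy two positions; all others one. If
    ``n_empty`` is None the remaining capacity is filled with EMPTY positions.
    """
    capacity = spec.density * n_plates
    if strain_ids is None:
        strain_ids = [f"JW{i:04d}" for i in range(1, n_strains + 1)]
    if len(strain_ids) != n_strains:
        raise ValueError("strain_ids length must equal n_strains")
    if n_duplicates > n_strains:
        raise ValueError("cannot duplicate more strains than exist")
    occupied = n_strains + n_duplicates
    if n_empty is None:
        n_empty = capacity - occupied
    total = occupied + n_empty
    if total > capacity or n_empty < 0:
        raise PlateCapacityError(
            f"{n_strains} strains + {n_duplicates} duplicates + {n_empty} empty "
            f"= {occupied + max(n_empty, 0)} positions exceed capacity "
            f"{capacity} ({n_plates} plate(s) x {spec.density})"
        )
    if total != capacity:
        raise PlateCapacityError(
            f"positions ({total}) must fill capacity ({capacity}) exactly; "
            "pass n_empty=None to pad with EMPTY"
        )

    rng = np.random.default_rng(seed)
    dup = rng.choice(n_strains, size=n_duplicates, replace=False)
    labels = list(strain_ids) + [strain_ids[i] for i in dup] + [EMPTY] * n_empty
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)

    plate = np.repeat(np.arange(n_plates), spec.density)
    rows = np.tile(np.repeat(np.arange(1, spec.n_rows + 1), spec.n_cols), n_plates)
    cols = np.tile(np.tile(np.arange(1, spec.n_cols + 1), spec.n_rows), n_plates)
    return pd.DataFrame(
        {
            "plate_id": [f"plate{p + 1}" for p in plate],
            "row": rows,
            "col": cols,
            "strain_id": labels,
        }
    )


def default_screen_truth(
    strain_ids,
    seed: int = 0,
    n_high: int = 22,
    n_low: int = 4,
    n_artifact: int = 10,
    high_factor_range: tuple[float, float] = (3.0, 4.0),
    top_high_factor: float = 6.0,
    low_factor_range: tuple[float, float] = (0.25, 0.4),
    strain_cv: float = 0.25,
    **kwargs,
) -> ScreenTruth:
    """Build the default screen truth: planted hits, artifacts and baselines.

    Defaults mirror the screen's structure: 22 fluorescence-up strains (low
    ligand) at >= 3x with the strongest planted at ~2x the others, 4
    fluorescence-down strains (high ligand) at <= 0.4x, and 10 artifact
    strains whose shift appears identically in the WT and control reporters.
    """
    strain_ids = list(strain_ids)
    rng = np.random.default_rng(seed)
    n_special = n_high + n_low + n_artifact
    if n_special > len(strain_ids):
        raise ValueError("more planted effects than strains")
    chosen = rng.choice(len(strain_ids), size=n_special, replace=False)
    high = [strain_ids[i] for i in chosen[:n_high]]
    low = [strain_ids[i] for i in chosen[n_high : n_high + n_low]]
    artifact = [strain_ids[i] for i in chosen[n_high + n_low :]]

    riboswitch = {}
    for j, s in enumerate(high):
        riboswitch[s] = top_high_factor if j == 0 else float(
            rng.uniform(*high_factor_range)
        )
    for s in low:
        riboswitch[s] = float(rng.uniform(*low_factor_range))
    art = {}
    for j, s in enumerate(artifact):
        art[s] = 3.0 if j % 2 == 0 else 0.3
    sigma = np.sqrt(np.log1p(strain_cv**2))
    baseline = {
        s: float(v)
        for s, v in zip(
            strain_ids,
            np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(strain_ids))),
        )
    }
    return ScreenTruth(
        riboswitch_effect=riboswitch,
        artifact_effect=art,
        strain_baseline=baseline,
        seed=seed,
        **kwargs,
    )


def edge_gradient(
    rows: np.ndarray,
    cols: np.ndarray,
    spec: PlateSpec,
    amplitude: float,
    decay_cells: int = 4,
) -> np.ndarray:
    """Multiplicative border gradient at 1-based grid positions.

    A smooth (half-cosine) function of the Chebyshev distance to the nearest
    plate edge: ``amplitude`` at the border ring, 1 from ``decay_cells``
    rows/cols inward.
    """
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    d = np.minimum.reduce(
        [rows - 1, cols - 1, spec.n_rows - rows, spec.n_cols - cols]
    ).astype(float)
    x = np.minimum(d, decay_cells) / decay_cells
    return 1.0 + (amplitude - 1.0) * 0.5 * (1.0 + np.cos(np.pi * x))


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    # mean-1 lognormal so noise does not bias totals
    return rng.lognormal(-sigma**2 / 2, sigma, size=n)


def plant_colony_truth(
    plate_map: pd.DataFrame,
    spec: PlateSpec,
    truth: ScreenTruth,
    reporter: str = "WT",
    timepoint: str = "24h",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Planted per-colony biomass and fluorescence totals for one or more plates.

    Biomass = base x growth-gradient x lognormal(cv). Fluorescence scales with
    the realized biomass and additionally carries the strain baseline, the
    artifact effect (both reporters), the riboswitch effect (WT reporter only)
    and the fluorescence border gradient, times its own lognormal(cv) factor —
    so the fluorescence/biomass ratio has CV ``noise_cv`` and a planted border
    gradient of ``edge_amplitude / biomass_edge_amplitude``.
    """
    if reporter not in ("WT", "G31C"):
        raise ValueError("reporter must be 'WT' or 'G31C'")
    if timepoint not in ("4h", "24h"):
        raise ValueError("timepoint must be '4h' or '24h'")
    if rng is None:
        rng = np.random.default_rng([truth.seed, _subseed(reporter, timepoint)])

    df = plate_map.copy()
    scale = truth.growth_scale_4h if timepoint == "4h" else 1.0
    g_b = edge_gradient(
        df["row"], df["col"], spec, truth.biomass_edge_amplitude,
        truth.gradient_decay_cells,
    )
    g_f = edge_gradient(
        df["row"], df["col"], spec, truth.edge_amplitude, truth.gradient_decay_cells
    )
    n = len(df)
    noise_b = _lognormal_factors(rng, truth.noise_cv, n)
    noise_f = _lognormal_factors(rng, truth.noise_cv, n)

    strains = df["strain_id"].to_numpy()
    rib = np.array(
        [truth.riboswitch_effect.get(s, 1.0) if reporter == "WT" else 1.0
         for s in strains]
    )
    art = np.array([truth.artifact_effect.get(s, 1.0) for s in strains])
    base = np.array([truth.strain_baseline.get(s, 1.0) for s in strains])
    occupied = strains != EMPTY

    biomass = np.where(occupied, truth.base_biomass * scale * g_b * noise_b, 0.0)
    ratio0 = truth.base_fluor / truth.base_biomass
    fluor = np.where(
        occupied,
        biomass * ratio0 * rib * art * base * (g_f / g_b) * noise_f,
        0.0,
    )
    df["planted_biomass"] = biomass
    df["planted_fluor"] = fluor
    df["planted_ratio"] = np.where(occupied, fluor / np.where(biomass > 0, biomass, 1),
                                   np.nan)
    df["reporter"] = reporter
    df["timepoint"] = timepoint
    return df


def _render_channel(
    truth_df: pd.DataFrame,
    spec: PlateSpec,
    truth: ScreenTruth,
    values: np.ndarray,
    sizes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render colonies as Gaussian-profile disks whose pixel sums equal
    ``values``; disk radius scales with the square root of relative biomass."""
    h, w = spec.image_shape
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    ty, tx = truth.background_tilt
    img = truth.background_level + ty * yy + tx * xx + np.zeros((h, w))

    sigma0 = truth.colony_sigma_px
    rel = np.sqrt(np.maximum(sizes, 0.0) / truth.base_biomass)
    sigmas = sigma0 * np.sqrt(np.maximum(rel, 1e-6))
    rows = truth_df["row"].to_numpy()
    cols = truth_df["col"].to_numpy()
    for r, c, v, s in zip(rows, cols, values, sigmas):
        if v <= 0:
            continue
        cy, cx = spec.node_yx(int(r), int(c))
        rad = int(np.ceil(4 * s)) + 1
        y0, y1 = max(0, int(cy) - rad), min(h, int(cy) + rad + 1)
        x0, x1 = max(0, int(cx) - rad), min(w, int(cx) + rad + 1)
        py = np.arange(y0, y1)[:, None] - cy
        px = np.arange(x0, x1)[None, :] - cx
        kern = np.exp(-(py**2 + px**2) / (2 * s**2))
        ksum = kern.sum()
        if ksum > 0:
            img[y0:y1, x0:x1] += kern * (v / ksum)
    if truth.read_noise_sd > 0:
        img = img + rng.normal(0, truth.read_noise_sd, size=img.shape)
    vmax = 2**spec.bit_depth - 1
    img = np.clip(np.round(img), 0, vmax)
    return img.astype(np.uint16 if spec.bit_depth == 16 else np.uint8)


def simulate_colony_plates(
    plate_map: pd.DataFrame,
    spec: PlateSpec,
    truth: ScreenTruth,
    reporter: str = "WT",
    timepoint: str = "24h",
    replicate_id: str = "rep1",
    rng: np.random.Generator | None = None,
) -> tuple[list[PlateImagePair], pd.DataFrame]:
    """Render image pairs (one per plate in the map) plus the planted truth table."""
    pairs = []
    truths = []
    for plate_id, pmap in plate_map.groupby("plate_id", sort=True):
        if rng is None:
            prng = np.random.default_rng(
                [truth.seed, _subseed(plate_id, reporter, timepoint, replicate_id)]
            )
        else:
            prng = rng
        tdf = plant_colony_truth(pmap, spec, truth, reporter, timepoint, prng)
        biomass_img = _render_channel(
            tdf, spec, truth, tdf["planted_biomass"].to_numpy(),
            tdf["planted_biomass"].to_numpy(), prng,
        )
        fluor_img = _render_channel(
            tdf, spec, truth, tdf["planted_fluor"].to_numpy(),
            tdf["planted_biomass"].to_numpy(), prng,
        )
        pairs.append(
            PlateImagePair(biomass_img, fluor_img, str(plate_id), replicate_id,
                           timepoint, reporter)
        )
        truths.append(tdf)
    return pairs, pd.concat(truths, ignore_index=True)


def simulate_screen_tables(
    plate_map: pd.DataFrame,
    spec: PlateSpec,
    truth: ScreenTruth,
    reporter: str = "WT",
    timepoint: str = "24h",
    replicate_id: str = "rep1",
) -> pd.DataFrame:
    """Measurement-level screen simulation (no pixel rendering).

    Produces the same schema as image quantification — one row per position
    with integrated ``biomass_sum`` / ``fluor_sum`` — directly from the
    planted per-colony totals, for fast many-seed experiments on the
    normalization and hit-calling stages.
    """
    rng = np.random.default_rng(
        [truth.seed, _subseed("tables", reporter, timepoint, replicate_id)]
    )
    tdf = plant_colony_truth(plate_map, spec, truth, reporter, timepoint, rng)
    out = tdf[["plate_id", "row", "col", "strain_id"]].copy()
    out["replicate_id"] = replicate_id
    out["timepoint"] = timepoint
    out["reporter"] = reporter
    out["biomass_sum"] = tdf["planted_biomass"]
    out["fluor_sum"] = tdf["planted_fluor"]
    out["roi_area"] = float(int(0.8 * spec.pitch_px) ** 2)
    out["flags"] = np.where(out["strain_id"] == EMPTY, "EMPTY", "")
    return out


def simulate_growth_curves(
    truth: KineticsTruth,
    tpp_concs,
    t_end: float = 16.0,
    dt: float = 1.0 / 6.0,
    n_wells: int = 3,
    n_blanks: int = 3,
    construct: str = "thiC-gfp",
) -> pd.DataFrame:
    """Simulate plate-reader OD/fluorescence time series across a titration.

    Returns a long table ``well, construct, condition_molar, time_h, od600,
    fluorescence, is_blank``. Raw readings include the blank (medium) offsets;
    blank wells carry the offsets only. Additive Gaussian measurement noise on
    both channels.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end < dt:
        raise ValueError("t_end must cover at least one interval")
    rng = np.random.default_rng(truth.seed)
    t = np.arange(0.0, t_end + dt / 2, dt)
    od_true = truth.od0 + (truth.K - truth.od0) / (
        1.0 + np.exp(-truth.r * (t - truth.t_m))
    )
    # cumulative trapezoid of OD — reporter made per cell per hour
    cum_od = np.concatenate(
        [[0.0], np.cumsum((od_true[1:] + od_true[:-1]) / 2 * np.diff(t))]
    )

    frames = []
    widx = 0
    for c in tpp_concs:
        theta = (c**truth.hill_n) / (truth.K_half**truth.hill_n + c**truth.hill_n) \
            if c > 0 else 0.0
        rate = truth.leak + (1.0 - truth.leak) * (1.0 - truth.E_max * theta)
        f_true = truth.alpha * rate * cum_od
        for _ in range(n_wells):
            widx += 1
            od = truth.blank_od + od_true + rng.normal(0, truth.od_noise_sd, t.size)
            fl = truth.blank_fluor + f_true + rng.normal(
                0, truth.fluor_noise_sd, t.size
            )
            frames.append(
                pd.DataFrame(
                    {
                        "well": f"W{widx:03d}",
                        "construct": construct,
                        "condition_molar": float(c),
                        "time_h": t,
                        "od600": od,
                        "fluorescence": fl,
                        "is_blank": False,
                    }
                )
            )
    for _ in range(n_blanks):
        widx += 1
        od = truth.blank_od + rng.normal(0, truth.od_noise_sd, t.size)
        fl = truth.blank_fluor + rng.normal(0, truth.fluor_noise_sd, t.size)
        frames.append(
            pd.DataFrame(
                {
                    "well": f"W{widx:03d}",
                    "construct": construct,
                    "condition_molar": np.nan,
                    "time_h": t,
                    "od600": od,
                    "fluorescence": fl,
                    "is_blank": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
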