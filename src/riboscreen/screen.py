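"""Replicate combination, control normalization, and 1 ± k·SD hit calling.

The WT-reporter screen is normalized per strain by the binding-dead (G31C)
control screen, which cancels every fluorescence effect unrelated to ligand
sensing (plasmid copy number, autofluorescence, growth artifacts). The
resulting expression index is recentered at 1; because the riboswitch is an
OFF switch, indices far above 1 flag low-ligand strains (high fluorescence)
and indices far below 1 flag high-ligand strains.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import EMPTY

__all__ = [
    "combine_replicates",
    "control_normalize",
    "call_hits",
    "duplicate_concordance",
    "replicate_pearson",
    "render_outputs",
]

HIGH_FLUOR = "HIGH_FLUOR"  # high fluorescence -> low ligand (OFF switch)
LOW_FLUOR = "LOW_FLUOR"    # low fluorescence -> high ligand


def combine_replicates(tables) -> pd.DataFrame:
    """Per-strain mean/SD of corrected ratios across biological replicates.

    Duplicate positions of a strain are averaged within each replicate first;
    the cross-replicate mean and SD are then taken over replicate values.
    Returns columns ``strain_id, mean, sd, n``.
    """
    tables = list(tables)
    if len(tables) < 2:
        warnings.warn(
            "fewer than 2 replicates: SD reported as missing", stacklevel=2
        )
    per_rep = []
    for i, t in enumerate(tables):
        sub = t[(t["strain_id"] != EMPTY) & t["ratio_corrected"].notna()]
        g = sub.groupby("strain_id")["ratio_corrected"].mean()
        per_rep.append(g.rename(f"rep{i}"))
    wide = pd.concat(per_rep, axis=1)
    out = pd.DataFrame(
        {
            "strain_id": wide.index,
            "mean": wide.mean(axis=1).to_numpy(),
            "sd": wide.std(axis=1, ddof=1).to_numpy(),
            "n": wide.notna().sum(axis=1).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def control_normalize(wt: pd.DataFrame, g31c: pd.DataFrame) -> pd.DataFrame:
    """Per-strain WT / G31C expression index, recentered to median 1.

    Strains missing on either side are kept with an undefined index and a
    reason so they can be reported as unscored rather than silently dropped.
    """
    merged = wt.merge(
        g31c, on="strain_id", how="outer", suffixes=("_wt", "_ctrl")
    ).rename(
        columns={
            "mean_wt": "wt_mean", "sd_wt": "wt_sd", "n_wt": "wt_n",
            "mean_ctrl": "ctrl_mean", "sd_ctrl": "ctrl_sd", "n_ctrl": "ctrl_n",
        }
    )
    if merged.empty:
        raise ValueError("no shared strain universe between WT and control")
    ok = merged["wt_mean"].notna() & merged["ctrl_mean"].notna() \
        & (merged["ctrl_mean"] > 0)
    raw = np.where(ok, merged["wt_mean"] / merged["ctrl_mean"], np.nan)
    med = np.nanmedian(raw)
    merged["index"] = raw / med
    merged["reason"] = np.where(
        ok, "",
        np.where(merged["wt_mean"].isna(), "MISSING_WT", "MISSING_CTRL"),
    )
    return merged


def call_hits(
    index_table: pd.DataFrame,
    threshold_k: float = 5.0,
    robust_scale: bool = True,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Call hits at ``threshold_k`` population SDs from the index center of 1.

    The population scale is estimated over the full defined-index
    distribution; by default a robust (MAD-based) SD is used so the hit tail
    itself cannot inflate the threshold, with the plain sample SD available
    via ``robust_scale=False``. Because the index is a ratio with
    multiplicative noise, the default bands are symmetric on the log scale,
    ``exp(±k·SD_log)`` — indistinguishable from ``1 ± k·SD`` at small SD but
    with matched tail probabilities on both sides; ``log_scale=False`` gives
    the plain linear bands. Ties exactly at the threshold count as hits.
    Returns hits sorted by |sd_distance| with the scale and thresholds in
    ``attrs``.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be > 0")
    idx = index_table["index"].to_numpy(dtype=float)
    defined = np.isfinite(idx)
    if log_scale:
        defined &= idx > 0
    if defined.sum() < 10:
        raise ValueError(
            f"only {int(defined.sum())} defined indices; need >= 10 for a "
            "meaningful SD"
        )
    v = np.log(idx[defined]) if log_scale else idx[defined]
    if robust_scale:
        sd_pop = 1.4826 * float(np.median(np.abs(v - np.median(v))))
    else:
        sd_pop = float(np.std(v, ddof=1))
    if sd_pop == 0:
        raise ValueError("degenerate index distribution (SD = 0)")

    out = index_table.copy()
    if log_scale:
        band_lo = float(np.exp(-threshold_k * sd_pop))
        band_hi = float(np.exp(threshold_k * sd_pop))
        with np.errstate(invalid="ignore", divide="ignore"):
            out["sd_distance"] = np.log(out["index"]) / sd_pop
    else:
        band_lo = 1.0 - threshold_k * sd_pop
        band_hi = 1.0 + threshold_k * sd_pop
        out["sd_distance"] = (out["index"] - 1.0) / sd_pop
    hi = out["index"] >= band_hi
    lo = out["index"] <= band_lo
    out["direction"] = np.where(hi, HIGH_FLUOR, np.where(lo, LOW_FLUOR, ""))
    out["tpp_call"] = np.where(hi, "LOW_TPP", np.where(lo, "HIGH_TPP", ""))
    out["threshold_k"] = threshold_k
    hits = out[(hi | lo)].copy()
    hits = hits.reindex(
        hits["sd_distance"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    hits.attrs["sd_pop"] = sd_pop
    hits.attrs["bands"] = (band_lo, band_hi)
    hits.attrs["n_defined"] = int(defined.sum())
    return hits


def duplicate_concordance(tables, plate_map: pd.DataFrame):
    """Internal control: compare the two positions of duplicated strains.

    For every duplicated strain and replicate, reports the pair of corrected
    ratios and their log2 difference. Returns ``(pairs, summary)`` with the
    median absolute log2 difference and the fraction of pairs within 1.5-fold.
    """
    counts = plate_map[plate_map["strain_id"] != EMPTY]["strain_id"].value_counts()
    dup_strains = set(counts[counts >= 2].index)
    if not dup_strains:
        warnings.warn("plate map contains no duplicated strains", stacklevel=2)
        return pd.DataFrame(
            columns=["replicate_id", "strain_id", "value_a", "value_b",
                     "log2_diff"]
        ), {"n_pairs": 0, "median_abs_log2": float("nan"),
            "frac_within_1_5_fold": float("nan")}

    rows = []
    for i, t in enumerate(list(tables)):
        rep = t["replicate_id"].iloc[0] if "replicate_id" in t else f"rep{i + 1}"
        sub = t[t["strain_id"].isin(dup_strains) & t["ratio_corrected"].notna()]
        for strain, g in sub.groupby("strain_id"):
            v = g["ratio_corrected"].to_numpy()
            if v.size >= 2 and v[0] > 0 and v[1] > 0:
                rows.append((rep, strain, v[0], v[1], float(np.log2(v[0] / v[1]))))
    pairs = pd.DataFrame(
        rows, columns=["replicate_id", "strain_id", "value_a", "value_b",
                       "log2_diff"]
    )
    abs_l2 = pairs["log2_diff"].abs()
    summary = {
        "n_pairs": int(len(pairs)),
        "median_abs_log2": float(abs_l2.median()) if len(pairs) else float("nan"),
        "frac_within_1_5_fold": float((abs_l2 <= np.log2(1.5)).mean())
        if len(pairs) else float("nan"),
    }
    return pairs, summary


def replicate_pearson(tables) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-strain values across replicates."""
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 replicate tables")
    series = [
        t.set_index("strain_id")["mean"] if "mean" in t
        else t[(t["strain_id"] != EMPTY)]
        .groupby("strain_id")["ratio_corrected"].mean()
        for t in tables
    ]
    wide = pd.concat(series, axis=1, join="inner").dropna()
    if len(wide) < 3:
        raise ValueError(f"only {len(wide)} shared strains; need >= 3")
    wide.columns = [f"rep{i + 1}" for i in range(len(tables))]
    return wide.corr(method="pearson")


def render_outputs(
    index_table: pd.DataFrame,
    hits: pd.DataFrame,
    records: pd.DataFrame | None,
    outdir,
    threshold_k: float = 5.0,
) -> dict:
    """Write the index plot, per-plate heatmaps and hit lists.

    Returns a dict of written paths. Heatmap matrices are row x col per
    plate; hit CSVs are split HIGH/LOW and sorted by |sd_distance|.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    cols = [c for c in ["strain_id", "index", "sd_distance", "direction",
                        "tpp_call", "threshold_k"] if c in hits.columns]
    high = hits[hits["direction"] == HIGH_FLUOR][cols] if len(hits) else \
        pd.DataFrame(columns=cols)
    low = hits[hits["direction"] == LOW_FLUOR][cols] if len(hits) else \
        pd.DataFrame(columns=cols)
    for name, df in [("hits_high.csv", high), ("hits_low.csv", low)]:
        path = outdir / name
        df.to_csv(path, index=False)
        written[name] = path
    unscored = index_table[index_table["index"].isna()]
    path = outdir / "unscored.csv"
    unscored.to_csv(path, index=False)
    written["unscored.csv"] = path

    bands = hits.attrs.get("bands")
    defined = index_table[index_table["index"].notna()].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(defined.index, defined["index"], s=4, c="#3465a4", alpha=0.6)
    if bands:
        for band in bands:
            ax.axhline(band, ls=":", c="k", lw=1)
    ax.axhline(1.0, c="k", lw=0.5)
    ax.set_xlabel("strain (arrayed order)")
    ax.set_ylabel("expression index (WT / G31C)")
    path = outdir / "index_plot.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written["index_plot.png"] = path

    if records is not None:
        for plate_id, sub in records.groupby("plate_id"):
            mat = np.full((int(sub["row"].max()), int(sub["col"].max())), np.nan)
            mat[sub["row"] - 1, sub["col"] - 1] = sub["ratio_corrected"]
            fig, ax = plt.subplots(figsize=(6, 4))
            im = ax.imshow(mat, cmap="viridis")
            fig.colorbar(im, ax=ax, label="corrected ratio")
            ax.set_title(str(plate_id))
            path = outdir / f"heatmap_{plate_id}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written[path.name] = path
            np.savetxt(outdir / f"heatmap_{plate_id}.csv", mat, delimiter=",",
                       fmt="%.6g")
            written[f"heatmap_{plate_id}.csv"] = outdir / f"heatmap_{plate_id}.csv"
    return written
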