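#!/usr/bin/env python
"""Ratio computation and spatial normalization for all screen plates.

Turns every measurement table from 01_simulate_screen.py into
fluorescence/biomass ratios, removes the border/incubator trend per plate,
and reports the edge-effect statistics before and after correction. Writes
normalized records and QC under results/normalized.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

import riboscreen as rs

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "screen_data"
OUT = ROOT / "results" / "normalized"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = rs.PlateSpec()
    qc_all = {}
    for path in sorted(DATA.glob("measurements_*.csv")):
        table = pd.read_csv(path)
        rec = rs.spatial_normalize(rs.compute_ratio(table), spec)
        rec.to_csv(OUT / path.name.replace("measurements", "normalized"),
                   index=False)
        qc_all[path.stem] = rs.plate_qc(rec, spec)

        d = np.minimum.reduce([rec["row"] - 1, rec["col"] - 1,
                               spec.n_rows - rec["row"],
                               spec.n_cols - rec["col"]])
        ok = rec["ratio_corrected"].notna()
        pre = spearmanr(rec.loc[ok, "ratio"], d[ok]).statistic
        post = spearmanr(rec.loc[ok, "ratio_corrected"], d[ok]).statistic
        print(f"{path.stem}: edge-distance Spearman {pre:+.3f} -> {post:+.3f}, "
              f"median corrected ratio "
              f"{np.nanmedian(rec['ratio_corrected']):.6f}")
    with open(OUT / "qc.json", "w") as fh:
        json.dump(qc_all, fh, indent=2, sort_keys=True)
    print(f"normalized records and QC -> {OUT}")


if __name__ == "__main__":
    main()
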