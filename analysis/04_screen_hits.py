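#!/usr/bin/env python
"""Expression index and hit calling for the synthetic screen.

Combines the three replicates per reporter, normalizes the WT screen by the
binding-dead control into the per-strain expression index, calls hits at
1 +/- 5 SD, and runs the internal controls (replicate Pearson, duplicated
strains). Writes the index, hit lists and plots under results/screen.
"""

from pathlib import Path

import pandas as pd

import riboscreen as rs
from riboscreen import io as rio

ROOT = Path(__file__).resolve().parents[1]
NORM = ROOT / "results" / "normalized"
OUT = ROOT / "results" / "screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pmap = rio.read_plate_map(ROOT / "results" / "screen_data" / "plate_map.csv")
    normalized = {
        reporter: [pd.read_csv(p) for p in
                   sorted(NORM.glob(f"normalized_{reporter}_rep*.csv"))]
        for reporter in ("WT", "G31C")
    }
    per = {rep: rs.combine_replicates(tables)
           for rep, tables in normalized.items()}
    index = rs.control_normalize(per["WT"], per["G31C"])
    hits = rs.call_hits(index, 5.0)
    index.to_csv(OUT / "index.csv", index=False)

    pearson = rs.replicate_pearson(normalized["WT"])
    pearson.to_csv(OUT / "pearson.csv")
    pairs, dup = rs.duplicate_concordance(normalized["WT"], pmap)
    pairs.to_csv(OUT / "duplicates.csv", index=False)
    records = pd.concat(normalized["WT"], ignore_index=True)
    rs.render_outputs(index, hits, records, OUT, 5.0)

    n_high = (hits["direction"] == "HIGH_FLUOR").sum()
    n_low = (hits["direction"] == "LOW_FLUOR").sum()
    lo, hi = hits.attrs["bands"]
    print(f"{index['index'].notna().sum()} scored strains, "
          f"index SD (robust, log) = {hits.attrs['sd_pop']:.4f}, "
          f"5 SD bands = [{lo:.3f}, {hi:.3f}]")
    print(f"hits: {n_high} HIGH fluorescence (low ligand), "
          f"{n_low} LOW fluorescence (high ligand)")
    print(f"top HIGH hit: {hits.iloc[0]['strain_id']} at index "
          f"{hits.iloc[0]['index']:.2f}")
    print(f"replicate Pearson r (WT): "
          f"{pearson.values[0, 1]:.3f}, {pearson.values[0, 2]:.3f}, "
          f"{pearson.values[1, 2]:.3f}")
    print(f"duplicated strains: {dup['n_pairs']} pairs, median |log2 diff| = "
          f"{dup['median_abs_log2']:.3f}, "
          f"{dup['frac_within_1_5_fold']:.1%} within 1.5-fold")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
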