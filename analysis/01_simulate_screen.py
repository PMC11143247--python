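#!/usr/bin/env python
"""Generate the synthetic reporter screen: plate maps, truth, measurements.

Builds the default study conditions — ~3800 knockout strains over three
1536-density plates with 402 duplicated strains, three biological replicates
of both the WT and the binding-dead (G31C) reporter, a 1.5x fluorescence
border gradient and 10% colony noise, with 22 planted fluorescence-up (low
ligand), 4 fluorescence-down (high ligand) and 10 artifact strains — plus
one rendered example image pair, and writes everything under results/screen_data.
"""

from pathlib import Path

import riboscreen as rs
from riboscreen import io as rio

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "screen_data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = rs.PlateSpec()
    pmap = rs.generate_plate_map(spec, 3800, 402, n_plates=3, seed=SEED)
    rio.write_plate_map(OUT / "plate_map.csv", pmap)
    strains = sorted(set(pmap["strain_id"]) - {rs.EMPTY})
    truth = rs.default_screen_truth(strains, seed=SEED)

    n = 0
    for reporter in ("WT", "G31C"):
        for rep in ("rep1", "rep2", "rep3"):
            table = rs.simulate_screen_tables(pmap, spec, truth, reporter,
                                              "24h", rep)
            table.to_csv(OUT / f"measurements_{reporter}_{rep}.csv",
                         index=False)
            n += len(table)

    # one rendered image pair (plate 1, WT, rep1) for the image-analysis stage
    plate1 = pmap[pmap["plate_id"] == "plate1"]
    pairs, planted = rs.simulate_colony_plates(plate1, spec, truth, "WT",
                                               "24h", "rep1")
    rio.write_image(OUT / "plate1_WT_rep1_24h_biomass.tif",
                    pairs[0].biomass_image)
    rio.write_image(OUT / "plate1_WT_rep1_24h_fluor.tif",
                    pairs[0].fluor_image)
    planted.to_csv(OUT / "plate1_WT_rep1_planted_truth.csv", index=False)

    print(f"wrote {n} colony measurements (2 reporters x 3 replicates x "
          f"3 plates x {spec.density} positions)")
    print(f"planted effects: {sum(v > 1 for v in truth.riboswitch_effect.values())} "
          f"fluorescence-up, {sum(v < 1 for v in truth.riboswitch_effect.values())} "
          f"fluorescence-down, {len(truth.artifact_effect)} artifacts")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
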