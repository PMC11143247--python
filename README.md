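# riboscreen

Analysis pipeline for riboswitch-biosensor screens in *Escherichia coli*:
genome-scale colony-array fluorescence screens read out through a
TPP (thiamin pyrophosphate)-sensing riboswitch reporter, and plate-reader
fluorescence/OD kinetics of the same biosensor.

## The problem

A TPP riboswitch placed upstream of *gfp* turns every cell into a metabolite
sensor: the *thiC* riboswitch is an OFF switch, so **high fluorescence means
low intracellular TPP** and vice versa. Pinning a knockout collection
(~3800–4000 strains) carrying this reporter onto 1536-density agar plates and
imaging each plate in white light (biomass) and fluorescence turns the
collection into a genome-scale screen for genes that perturb TPP metabolism.
Getting from plate images to a trustworthy hit list requires:

1. **Colony quantification** — background removal, rigid-grid ROI placement,
   and *integrated intensity* (the pixel sum, not the mean) per colony and
   channel.
2. **Normalization** — the fluorescence/biomass ratio per colony, then
   removal of spatial border/incubator trends ("edge effect") per plate,
   rescaled to plate median 1.
3. **Control normalization** — every strain's WT-reporter value is divided by
   its value with a binding-dead aptamer mutant (G31C) reporter, which
   cancels all fluorescence variation unrelated to TPP sensing (plasmid copy
   number, autofluorescence, growth artifacts).
4. **Hit calling** — the resulting expression index is centered at 1; hits
   are strains beyond 1 ± k·SD (k = 5) of the index distribution,
   high-fluorescence hits meaning low TPP and low-fluorescence hits meaning
   high TPP.

The index for strain *s* is

```
index(s) = (WT ratio_corrected, replicate mean) / (G31C ratio_corrected, replicate mean)
```

recentered so that median(index) = 1, with hit bands `exp(±k·SD_log)` where
`SD_log` is the robust (MAD-based) SD of log index — numerically the familiar
1 ± k·SD dotted lines at screen-typical SDs, with equal tail probability on
both sides of a ratio statistic.

A synthetic-data module generates plate images, plate maps and plate-reader
curves with planted ground truth (riboswitch effects, artifact strains,
duplicated strains, border gradients, logistic growth with Hill-type
TPP-dependent repression), so every stage of the pipeline is verifiable
end to end without any external data.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(fixed seed). `01` simulates the screen, `02` quantifies a rendered plate
image pair, `03` normalizes all plates, `04` builds the index and calls hits,
`05` analyzes reporter kinetics:

```sh
python analysis/01_simulate_screen.py
python analysis/02_quantify_images.py
python analysis/03_normalize_screen.py
python analysis/04_screen_hits.py
python analysis/05_kinetics.py
```

which prints (abridged):

```
grid fit: origin=(24.0, 24.0) px, pitch=(20.00, 20.00) px, 92% of nodes supported by a colony peak
measured vs planted: biomass r=0.9995, fluorescence r=0.9999
measurements_WT_rep1: edge-distance Spearman -0.412 -> +0.000, median corrected ratio 1.000000
3800 scored strains, index SD (robust, log) = 0.0785, 5 SD bands = [0.675, 1.481]
hits: 22 HIGH fluorescence (low ligand), 4 LOW fluorescence (high ligand)
top HIGH hit: JW1814 at index 5.77
replicate Pearson r (WT): 0.913, 0.923, 0.917
duplicated strains: 1206 pairs, median |log2 diff| = 0.144, 99.5% within 1.5-fold
stationary-phase fold regulation (reference = no ligand):
         100 nM: 1.31
        1000 nM: 1.89
max repression 0.48, half-repression at 100 nM
```

Reading this: the grid fitter recovered the planted geometry exactly;
integrated intensities track the planted colony totals at r > 0.999; the
border effect (Spearman −0.41 between ratio and edge distance) is removed to
~0; the screen recovers exactly the 22 planted fluorescence-up and 4
fluorescence-down strains while the 10 planted artifact strains (shifted
identically in WT and G31C) are never called; and the kinetics pipeline
recovers ~1.9-fold maximal repression with half-repression near the planted
100 nM.

A single-command demo (`riboscreen demo --out demo_out --seed 7`) runs a
smaller image-rendered screen plus kinetics; `riboscreen quantify/screen/
kinetics` expose the individual stages for real image and plate-reader files.

## Layout

```
src/riboscreen/
  simulate.py     synthetic plates, maps, truth, growth curves
  quantify.py     background, grid fitting, integrated intensities
  normalize.py    fluorescence/biomass ratio, spatial correction, QC
  screen.py       replicate combination, WT/G31C index, hit calling, controls
  kinetics.py     blank correction, F/OD, phases, fold regulation, titrations
  pipeline.py     orchestration, configs, manifests
  experiments.py  planted-truth validation experiments
  cli.py          riboscreen {simulate,quantify,screen,kinetics,demo}
analysis/         numbered narrative drivers (see worked example)
docs/methods.md   models, assumptions, parameter choices, limitations
```
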