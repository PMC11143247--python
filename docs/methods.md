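# Methods

This note documents the models, the parameter choices and their rationale,
what the synthetic data does and does not emulate, and the numerical
decisions made where the design was genuinely open.

## Synthetic screen model

### Plate geometry and maps

Plates are 32 × 48 grids (1536 density) rendered at 20 px pitch with a 24 px
margin into 16-bit grayscale images (668 × 988 px). The default screen
arrays ~3800 strains over three plates with 402 strains duplicated (two
positions each) and the remaining positions empty, mirroring the structure
of a pinned knockout-collection screen with its duplicated-strain internal
control. Maps are uniformly shuffled per seed.

### Planted per-colony totals

For colony *i* at grid position with Chebyshev edge distance *d*:

```
biomass_i = B0 · g_b(d) · LN(cv)            (white-light integrated total)
fluor_i   = biomass_i · (F0/B0) · r_i · a_i · b_i · g_f(d)/g_b(d) · LN(cv)
```

* `B0 = 5·10⁴`, `F0 = 2·10⁴` arbitrary integrated units (peak pixel values
  ~900 of 65535, far from saturation).
* `g_f` is the fluorescence border gradient: a half-cosine ramp from
  `edge_amplitude` (default 1.5) at the outermost ring to 1 at ≥ 4 rings
  inward; `g_b` the analogous growth gradient (default 1.0). The true
  spatial form of real border/incubator effects is unpublished; this ramp is
  an explicit stand-in. Because fluorescence is modelled proportional to
  realized biomass, the fluorescence/biomass ratio carries the planted
  gradient `g_f/g_b` and a single lognormal factor — so the ratio CV equals
  `noise_cv` (default 10%).
* `r_i` is the riboswitch effect (strain-specific, applied only to the
  functional WT reporter): 22 fluorescence-up strains at 3–4× with the
  strongest planted at 6× (≈2× the runner-up, mirroring the dominant top hit
  of a real screen), 4 fluorescence-down strains at 0.25–0.4×.
* `a_i` is the artifact effect, applied identically to WT and binding-dead
  (G31C) reporters (10 strains at 3× or 0.3×) — e.g. mutants that perturb
  reporter-plasmid replication.
* `b_i` is a per-strain baseline expression factor shared by both reporters
  (lognormal, CV 25%): real strains differ in expression for reasons
  unrelated to the sensed ligand. It cancels exactly in the WT/G31C index
  but gives replicate-to-replicate Pearson correlations a realistic
  biological-signal component (r ≈ 0.92 at the defaults).

Colonies are rendered as Gaussian disks (σ = 2.5 px at `B0`, radius scaling
with √biomass so integrated intensity stays proportional to the planted
total), on a background plane (level 100, optional tilt) with additive read
noise (SD 2); empty positions render background only. At 4 h biomass is 10%
of the 24 h value; the screen index uses the 24 h images.

### What the generator does not emulate

Pinning defects beyond random failures, agar texture, colony morphology or
shape classes, optical vignetting, inter-plate batch effects beyond the
per-plate gradient, and channel misregistration. Passing tests therefore
demonstrate correctness of the *analysis* under the stated statistical
structure, not robustness to every real-world artifact.

## Image quantification

* **Background**: a large-window (2 × pitch + 1 px) running low percentile
  (10th) computed on a strided subsample and bilinearly interpolated back —
  a rolling-ball-like lower envelope. A plain large-window median tracks the
  summed Gaussian tails of neighbouring colonies and biases colony sums by
  ~1% in a neighbourhood-dependent way; the lower envelope reduces this to
  < 0.1% (measured zero-noise recovery r = 1.0000).
* **Grid**: pinned arrays are rigid, so a fixed-pitch grid is fitted by
  maximizing the background-subtracted row/column projection profiles over a
  per-axis search of origin (± 0.6 pitch) and pitch (± 0.5 px, refined to
  0.01 px). Grid fitting fails loudly when fewer than 25% of expected nodes
  show a peak above 6 robust SDs of the residual image.
* **ROIs**: squares of side 0.8 × pitch centered on nodes (non-overlapping);
  the measurement is the pixel **sum** (integrated intensity), never the
  mean. ROIs truncated by the image edge are flagged; colonies with > 5%
  saturated pixels are flagged (QC only).
* Channels are assumed registered (same imaging session); biomass comes from
  the white-light image, fluorescence from the fluorescence image, same ROIs.

## Spatial normalization

`ratio = fluor_sum / biomass_sum` per colony; EMPTY positions and colonies
below 10% of the plate-median biomass (failed pinnings) are excluded with
reasons and propagate as missing values, never zeros.

The per-plate spatial trend is the product of two robust components:

1. **Edge-ring correction**: the median of each of the 4 outer Chebyshev
   rings relative to the interior median. Border effects on pinned plates
   are ring-structured (each ring shares nutrient and incubator exposure);
   no generic local smoother can follow a ring pattern at plate corners — a
   running median or local polynomial leaves up to ~10% corner error and is
   not idempotent, which is why the ring term exists.
2. **Local-quadratic robust trend** (window 13, lowess-style bisquare
   weights, 3 iterations, scale floored at 1% of the local level) over the
   ring-corrected grid, for smooth incubator gradients and tilts. Quadratic
   rather than linear/median to avoid boundary bias; window 13 chosen so the
   smoother's own sampling noise (~2–3%) stays well below the colony CV
   while single-colony outliers (planted 3× hits) are preserved intact.

Corrected ratios are rescaled so the plate median over included colonies is
exactly 1. On noise-free plates the correction is idempotent to ~1e-10; with
10% colony noise a second application re-fits ~2% of sampling noise, which
is a property of any smoother whose window is small enough to track the
border trend.

## Screen index and hit calling

Duplicate positions of a strain are averaged within each replicate first;
replicate means and SDs are taken across the ≥ 3 biological replicates. The
expression index is the per-strain ratio WT / G31C, recentered to median 1
(median, not mean, so one-sided hit tails cannot shift the center). Strains
missing on either side are reported as unscored, never dropped silently.

Hits at `k = 5` population SDs use a **robust scale** (1.4826 × MAD) of
**log index**, with bands `exp(±k·SD_log)`:

* Robust, because the planted hit tail itself would otherwise inflate a
  plain SD (from ~0.08 to ~0.17 under the default screen), pushing the lower
  band below zero and making fluorescence-down hits unrecoverable.
* Log-scale, because the index is a ratio with multiplicative noise: linear
  `1 ± 5·SD` bands sit at ~4.1 log-sigma on the right tail (≈0.08 false
  positives per 3800-strain screen) but ~6 on the left; log bands equalize
  both tails at the nominal `2Φ(−5) ≈ 5.7·10⁻⁷`. At screen-typical SDs
  (`SD_log ≈ 0.08`) the bands are numerically the familiar 1 ± 5·SD lines.
* Plain-SD and linear-band behaviour remain available
  (`robust_scale=False`, `log_scale=False`).
* Ties exactly on a band are hits (≥ / ≤). Direction mapping is fixed by the
  OFF-switch logic: HIGH fluorescence ⇒ low ligand, LOW ⇒ high ligand.

Internal controls: pairwise replicate Pearson on shared strains; duplicated
strains compared position-against-position (unaveraged) with the median
|log2 difference| and the fraction of pairs within 1.5-fold; per-plate QC
with border-vs-center ratios before and after correction.

## Kinetics model and analysis

Growth is logistic, `OD(t) = od0 + (K − od0)/(1 + e^{−r(t − t_m)})`
(defaults od0 0.02, K 0.8, r 1.0 h⁻¹, t_m 5 h). Fluorescence accumulates at
rate `α·OD(t)·(leak + (1 − leak)(1 − E_max·θ(c)))` with Hill occupancy
`θ(c) = cⁿ/(K_halfⁿ + cⁿ)` (defaults α 1500 AU/OD/h, E_max 0.5, K_half
100 nM, n 2, leak 0.05 for reporter-independent background). The saturating
fold repression is `1/(1 − E_max(1 − leak))` ≈ 1.90 at the defaults,
matching the ~2-fold regulation of a transcriptional riboswitch–GFP fusion;
K_half in the 10⁻⁷ M range matches sensing that saturates by a few hundred
nM. Blank wells carry the medium offsets (OD 0.04, 30 AU); measurement
noise is additive Gaussian (OD SD 0.003, 5 AU).

Analysis: time-matched median-blank subtraction (clipped at 0); pointwise
F/OD masked below an OD floor of 0.02 (blank-noise blowup); the exponential
readout at the first half-amplitude OD crossing, linearly interpolated —
equal to the inflection time for a symmetric logistic — with a phase error
raised when the OD amplitude is within 8× the sample-to-sample noise scale;
the stationary readout at 16 h; normalization to the no-ligand reference
(reference ≡ 1, fold regulation its reciprocal). The dose-response summary
reports maximal fractional repression, the lowest concentration reaching
90% of it, a log-interpolated half-repression concentration, and a count of
monotonicity violations. Flat responses (< 5% repression) report these as
undefined rather than inventing a midpoint.

## Problem sizes and determinism

Validation experiments run at the study's native scale — 3800 strains ×
3 plates × 2 reporters × 3 replicates — at measurement level (planted
integrated totals from the same truth model the renderer consumes), with the
image route validated on full 1536-colony rendered plates; 20 seeds for hit
recovery and 100 for the null false-positive rate. All randomness flows from
explicit integer seeds through per-purpose streams (stable CRC-derived
substream keys), so identical configurations reproduce byte-identical output
bundles, which the run manifest (SHA-256 per output file) makes checkable.

## Known limitations

* The spatial model and its correction assume multiplicative, ring-plus-
  smooth trends; pathological patterns (e.g. a failed pin row) are excluded
  by the growth floor, not modelled.
* The exponential-phase readout is a single interpolated time point; a
  window average (available as an option upstream of `phase_values`) would
  be more robust to plate-reader glitches but is not the default.
* The G31C index removes strain-specific artifacts only insofar as they are
  equal in both reporters; reporter-specific artifacts would survive.
* Hit thresholds assume a unimodal, roughly symmetric log-index null; a
  strongly contaminated null (many true effects) would call for the plain-SD
  option plus manual review.
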