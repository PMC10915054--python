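# Methods

## Problem and model

A water-limited leaf closes its stomata, loses evaporative cooling and warms
relative to a well-watered leaf under the same conditions. The pipeline
classifies single-leaf radiometric thermal images (per-pixel °C grids,
nominally 640×480 from a handheld camera, leaf against a paper backdrop)
into well-watered (WW) vs dry-down (DD) in three stages: non-parametric
leaf segmentation, robust thermal summarization, and supervised
classification.

The segmentation is "non-parametric" in the sense that its threshold adapts
to each image: after removing the image's continuous (DC) Fourier component
and taking the Sobel gradient magnitude δ, the quartiles q1, q3 of δ define
Tukey fences thr_dw = q1 − 1.5·IQR and thr_up = q3 + 1.5·IQR, and mask
pixels are the fence outliers. Gradient magnitudes are non-negative and in
typical images q1 − 1.5·IQR < 0, so the lower fence alone is vacuous; the
default binarization is therefore two-sided, with a `low_only` mode
retaining the lower-fence-only rule for comparison (on typical scenes it
yields an empty mask and a segmentation failure, which the test suite
documents). The raw mask — strong edge responses concentrated on the leaf
outline — is dilated (disk, radius 3), hole-filled, eroded with the same
element, and reduced to its largest 8-connected component. A final
component below `min_area` = 50 px is treated as a segmentation failure
rather than a leaf.

### High-pass filter semantics

The filter zeroes Fourier coefficients with magnitude ≥ |DC|. In natural
thermal images |DC| dominates every other coefficient, so this removes
exactly the mean. Two edge cases are fixed deliberately:

- A numerically zero DC (e.g. the filter's own output) is treated as "no
  continuous component present" and the filter is the identity; comparing
  against a zero threshold would instead wipe the whole spectrum. This makes
  the operation idempotent.
- The comparison is on the complex magnitude spectrum (DC-centred view only
  affects visualization, not the mask), and the real part of the inverse
  transform is returned.

Segmentation is consequently invariant to adding a constant temperature to
the whole frame, which the suite asserts at ±10 °C.

### Feature extraction

Masked temperatures pass once (no iteration) through the same 1.5·IQR fence
filter; values strictly outside the fences are dropped, ties at a fence are
kept. Under normality this removes ≈ 0.7 % of genuine leaf pixels, but it
removes *all* pixels of a thin backdrop ring leaking into the mask when the
leaf/backdrop contrast is large — the operational meaning of "robust to
small mask misalignments", asserted as a 1-px-dilation invariance test at
5 °C contrast. Nine indicators are then computed: mean, standard deviation
(sample, n−1; the population/sample choice is configurable and unstated in
the underlying method description), median, 25th/75th percentiles, IQR,
max, min, range. Quantiles use linear (type-7) interpolation everywhere —
segmentation fences, feature quantiles, outlier fences — so all fences are
reproducible from one convention. A sample with fewer than 10 surviving
pixels raises an insufficient-data error.

### Screening

Each feature is compared WW-vs-DD with a two-sided two-sample
Kolmogorov–Smirnov test (asymptotic p-values; the exact method is available
for small samples); features with p ≥ α = 0.05 are dropped. No
multiple-testing correction is applied, matching the procedure being
reproduced. Screening runs on the full labeled table before the
train/validation split — the documented order of the original procedure —
which leaks label information across the split; callers wanting the
leakage-free variant can screen on training rows only and pass the kept set
explicitly.

### Classification

Both pipelines are sklearn compositions: standardization → mutual-information
SelectKBest → classifier, tuned by randomized search over

- RF: max_depth {3,5,7,10}, min_samples_leaf {2,5,10}, n_estimators
  {100,300}, K {3,5,7,9}
- MLP: hidden {25,50,100}, L2 α {1e-4,1e-3}, initial step {1e-3,1e-2},
  K {3,5,7,9}

with stratified 10-fold CV (25 candidate draws by default) and refit on all
of T. Defaults are the reference winners: RF K=3, depth 5, min leaf 5; MLP
K=7, one hidden layer of 50, Adam, constant learning rate, ≤500 epochs, no
early stopping. Scaler and selector are fitted on training rows only.
The split is stratified by class; |T| = floor(0.75·N). Inside the CV
pipelines the scaler is sklearn's (population sd); the standalone
`standardize()` uses sample sd (n−1) — the distinction is immaterial at the
intended sample sizes and both are seeded deterministically. Reports print
per-class precision/recall/F1/support at two decimals and overall accuracy
to the nearest percent; a per-class "weighted accuracy" has no standard
definition and is not emitted.

### Physiological cross-check

Predictions are joined to per-sample physiology (soil VWC %, PSII
efficiency, leaf water potential) and a sample is flagged when a trait falls
outside the 1.5·IQR fences of its own treatment group — the same robust
device as everywhere else, standing in for a visual outlier judgement. The
output is flag rates by outcome tag (DD_DD, DD_WW, WW_DD, WW_WW);
associational only.

## Synthetic scenes: what they emulate and what they don't

The generator renders an elliptical, lobed (3-lobe) or okra-like (5 narrow
lobes) leaf of i.i.d. N(leaf_temp_mean, leaf_temp_sd²) pixels plus a smooth
0.5 °C base-to-tip trend, on a uniform backdrop, then applies Gaussian
optics blur and additive sensor noise. Defaults: 120×160 px frames (the
temperature structure, not the camera resolution, is what downstream stages
consume; smaller frames keep cohort-scale runs fast), backdrop 22 °C, leaf
27 °C, leaf sd 0.3 °C, noise 0.15 °C, blur 1 px. Cohorts jitter leaf size,
shape, rotation, centre and mean temperature (sd 0.4 °C) to mimic genotype
diversity, and warm DD leaves by a configurable offset, default +2 °C — a
plausible stomatal-closure effect size for a strong dry-down.

Not emulated: energy-balance physics, within-leaf vein/lobe temperature
structure beyond a linear trend, backdrop texture, camera vignetting or
drift, genotype-correlated morphology. Passing tests therefore demonstrate
that the pipeline recovers a known treatment signal under controlled
optics-like corruption — not field performance on real cotton imagery,
where genotypic temperature variation alone can exceed the treatment
effect.

## Numerical and design choices

- Quantiles: type-7 (linear interpolation) throughout.
- Sobel via edge-replicated correlation; central differences selectable.
- Component-size ties break to the smallest label (scan order).
- Fence multiplier 1.5 everywhere, configurable per call.
- Scene determinism: one `numpy` Generator per scene seeded from the spec;
  cohort and pipeline stage seeds derive from a single global seed via
  `SeedSequence` (CRC-tagged per stage), so a rerun is bit-identical.
- Degenerate inputs: constant frames (all-zero gradient) fail segmentation
  with diagnostics; constant feature columns are centered and flagged
  rather than scaled; zero-variance KS inputs return p = 1.

## Problem sizes used by the checks

Segmentation recovery uses 20 seeded scenes (5 °C contrast, 0.2 °C noise,
1-px blur; mean IoU ≥ 0.8 observed ≈ 0.85). KS calibration uses 1,000 null
repetitions at n = 200/group (rejection ≈ 0.05). End-to-end discrimination
uses 100 leaves per class: at +2 °C both classifiers sit near-perfect on
held-out leaves, far above the majority baseline, and at zero offset they
fall to chance. These cohort sizes match the scale of the motivating
dataset (≈ 200 leaves per treatment).

## Known limitations

- The two-sided fence binarization is a repair of an ambiguous published
  rule; `low_only` preserves the literal alternative but cannot segment
  typical scenes.
- Screening before the split leaks label information; kept as the default
  for procedural fidelity (see above).
- Single-leaf assumption: multiple leaves or backdrop clutter yield the
  largest component only.
- Asymptotic KS p-values are approximate below n ≈ 25 per group; use
  `method="exact"` there.
- The synthetic generator's simplifications above mean real-image
  performance must be validated separately.
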