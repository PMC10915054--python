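# thermoleaf

Leaf-level thermal image analysis for drought detection: segment a single
leaf out of a handheld radiometric thermal image, summarize its temperature
distribution with robust statistical indicators, and classify the plant's
watering treatment — well-watered (WW) vs dry-down (DD) — with random-forest
and multilayer-perceptron pipelines.

The package is aimed at plant phenotyping workflows where leaves are imaged
against a paper backdrop with a handheld thermal camera and exported as
per-pixel temperature grids (CSV). Water-limited leaves close their stomata,
lose evaporative cooling, and warm up; the pipeline turns that signal into a
binary hydration-status call per leaf.

## Method

For a temperature grid `I` (°C):

1. **High-pass filter.** Compute the 2D FFT of `I` and zero every Fourier
   coefficient whose magnitude is ≥ the magnitude of the DC (zero-frequency)
   coefficient — in practice exactly the DC term, i.e. the image mean. The
   real part of the inverse transform is the filtered image.
2. **Gradient.** `δ = sqrt(gx² + gy²)` with 3×3 Sobel operators (edge
   replication at the border).
3. **Leaf mask.** From all gradient values compute quartiles `q1, q3`,
   `IQR = q3 − q1`, and the Tukey fences
   `thr_dw = q1 − 1.5·IQR`, `thr_up = q3 + 1.5·IQR`. The binary mask is
   `M(i,j) = 1` where `δ(i,j) < thr_dw` or `δ(i,j) > thr_up`, refined by
   dilation → hole filling → erosion (disk, radius 3) and reduced to its
   largest connected component.
4. **Features.** Temperatures under `M` are outlier-filtered once with the
   same 1.5·IQR fence rule (robustness to mask misalignment), then
   summarized by nine indicators: mean, sd, median, 25th/75th percentiles,
   IQR, max, min, range.
5. **Screening.** Each indicator is compared between WW and DD with a
   two-sample Kolmogorov–Smirnov test; features with `p ≥ α = 0.05` are
   dropped.
6. **Classification.** Stratified 75/25 split into training (T) and
   validation (V); per-feature standardization to N(0,1); mutual-information
   selection of the K most informative features (K=3 for RF, K=7 for MLP);
   randomized hyperparameter search with stratified 10-fold CV on T; report
   of per-class precision/recall/F1, confusion matrix and accuracy on V.

Because no public leaf-image dataset accompanies the method, the package
includes a synthetic scene generator (`thermoleaf.synthetic`) producing
leaf-shaped warm regions on a paper backdrop with known ground-truth masks
and a configurable DD warming offset (+2 °C by default), so every stage is
testable end to end.

## Worked example

```sh
python examples/01_simulate_and_segment.py
```

```
frame: 120x160 px, T in [21.1, 27.8] °C
true leaf area: 2819 px
segmented area: 3393 px
IoU vs ground truth: 0.831
```

The IoU (intersection over union, in [0,1]) scores the recovered mask
against the generator's ground truth; ≥ 0.8 under 1-px blur and 0.2 °C
sensor noise means the quartile-fence segmentation found the leaf. Training
the classifiers on a 60+60 cohort with a +2 °C dry-down offset
(`examples/03_train_and_evaluate.py`) prints:

```
Classification report (rf)
 class precision  recall     f1  support
    DD      1.00    1.00   1.00       15
    WW      1.00    1.00   1.00       15
overall accuracy: 100% (30/30)

Classification report (mlp)
 class precision  recall     f1  support
    DD      1.00    0.93   0.97       15
    WW      0.94    1.00   0.97       15
overall accuracy: 97% (29/30)
```

i.e. on held-out leaves both pipelines recover the watering treatment nearly
perfectly when the class separation is 2 °C at low noise. The other examples
show KS feature screening (`02`) and the physiological plausibility check of
classifier outcomes (`04`).

The same functionality is exposed as a thin CLI:

```sh
thermoleaf simulate scenes/ --n-per-class 20 --dd-offset 2.0 --seed 1
thermoleaf run scenes/manifest.csv --out-dir run1 --seed 1
```

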