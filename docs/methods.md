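# Methods

## Scope and model

`ramanmargin` models a macroscopic line-scanning Raman imager pointed at a
two-tissue margin and the full analysis path from raw luminescence cube to
a classified margin map. The package's claims are about the *pipeline* —
preprocessing fidelity, feature-selection sparsity, classifier behavior,
margin localization — evaluated against simulated scenes with known ground
truth, plus the deterministic instrument arithmetic (geometry and photon
budget).

## The synthetic scene generator

Every cube is built as

```
cube = clean + background + noise + spikes
```

and the generator returns each term (plus the planted calibration, system
response, illumination and label map) so downstream stages can be tested
against known answers.

* **Tissue templates.** Sixteen Lorentzian bands (FWHM 10 cm⁻¹) at the
  porcine adipose/muscle positions between 620 and 1739 cm⁻¹. Muscle
  expresses the protein bands (620, 824, 853, 1001, 1604 cm⁻¹); adipose
  the lipid bands (967, 1082, 1298, 1346, 1739 cm⁻¹) with the shared
  1442 cm⁻¹ CH₂ band at ~2.2x the muscle intensity and the 1001 cm⁻¹
  phenylalanine band absent. Exact amplitudes are not published for this
  regime; they were chosen once so that (i) adipose has a visibly larger
  integrated Raman cross-section (its known property as the stronger
  scatterer, giving a Raman intensity-image class effect size > 2) while
  (ii) the raw luminescence shows essentially no class contrast.
* **Fluorescence background**: a fixed smooth fifth-order polynomial
  profile scaled to 5x the strongest band amplitude, so raw counts are
  background-dominated.
* **Noise**: zero-mean Gaussian with sd `sqrt(clean + background) /
  snr_scale`, the Gaussian approximation to shot noise, divided by
  `sqrt(n_frames)` after frame averaging (frames are drawn individually
  and averaged). `snr_scale` is 1.0 for muscle and 1.6 for adipose, giving
  adipose its higher observed SNR.
* **System response**: a smooth spectral roll-off times a mild spatial
  vignette, applied multiplicatively; the measured intensity standard is
  this response with 12–50%-deep, ≤3-px scratch dips multiplied in, so
  correction must smooth the standard before dividing.
* **Cosmic rays**: at most one single-channel positive spike per spectrum
  (Bernoulli per spectrum, default rate 0.01), amplitude 10–100x the local
  signal, uniform channel position.
* **Cross-margin bleed**: near-margin pixels of the non-adipose class
  receive an added fraction of the adipose clean spectrum decaying as
  `0.35 · exp(−d / 1.5 px)` with scan-axis distance *d* from the boundary,
  one-sided — emulating the spatially offset in-depth signal of the
  stronger scatterer. The magnitude of this effect is not quantified in
  the literature for this geometry; 0.35/1.5 px was chosen once as a
  sub-pixel-dominant but clearly measurable contamination.
* Default geometry: 40 lines x 42 positions x 341 channels, 400–1900 cm⁻¹,
  250 µm step, 9.5 mm line, 5 s/line; pure-tissue training images use
  10-frame averages, the margin image a single acquisition.

All randomness flows from the scene seed through `numpy.random.SeedSequence`
spawns; identical configs give bit-identical cubes.

What the generator does **not** emulate: intra-class biochemical
heterogeneity (each class is one template), margin thickness/mixing other
than the exponential bleed, detector nonlinearity and etaloning, focus
drift, and real acetaminophen/intensity-standard measurement noise.
Passing tests therefore demonstrate pipeline correctness and the
recoverability of planted structure at realistic SNR — not clinical
performance on real tissue.

## Preprocessing chain

Stages run in the fixed order: despike → calibrate → response-correct →
baseline-remove → SNV.

* **Cosmic-ray elimination.** A running median (width 5) is used as the
  local reference; channels exceeding it by both 8x the per-spectrum
  median absolute residual and 2x the local reference are replaced by
  linear interpolation across unflagged neighbors. A plain running median
  is *not* applied wholesale because at 4.4 cm⁻¹/channel the 10 cm⁻¹-FWHM
  bands span ~2.3 channels and a width-5 median halves their apexes
  (measured ~55% peak error); detection-plus-replacement leaves unflagged
  channels untouched. Residual spike excess is below 3σ of local noise for
  ≥95% of spikes; the exceptions sit on band apexes where any
  single-channel reconstruction errs by the local curvature.
* **Wavenumber calibration.** The six most prominent peaks
  (prominence-ranked, ≥3-channel separation, ties to lower pixel) of the
  acetaminophen reference are refined to sub-pixel positions by parabolic
  interpolation on log intensity (exact for Gaussian profiles), paired in
  order with the six reference shifts (default: the ASTM E1840
  fingerprint-region values 651.6, 857.9, 1168.5, 1236.8, 1323.9,
  1648.4 cm⁻¹ — configurable), and interpolated with a monotone cubic
  (PCHIP) spline, linearly extrapolated beyond the outer knots.
  Non-monotone knots raise; a planted +3 cm⁻¹ bowing is recovered to
  well under 1 cm⁻¹ at all anchors.
* **Response correction.** The standard measurement is smoothed with a 2-D
  Gaussian (σ = 2.5 px spatially and spectrally — wide enough to suppress
  ≤3-px scratches, narrow enough to keep the response shape), normalized
  to max 1 (preserving peak scale), and divided out of every scan line;
  a 1-px border of the cube is rejected where the kernel is ill-supported.
* **Baseline removal.** An iterated clipped fifth-order polynomial fit
  (5 iterations of fit-then-clip-to-min, settling under the peaks)
  followed by a rolling-ball pass on the residual: a grayscale opening
  with a spherical element of radius 16 channels whose height is the
  per-spectrum interquartile range (making the ball geometry commensurate
  with the intensity scale; height 0 degenerates to a flat min–max
  filter). The opening is computed by shift-accumulated erosion/dilation
  with boundary clipping and is tested for *exact* equality against an
  exhaustive min–max oracle. Note the opening is anti-extensive
  (background ≤ signal everywhere): it bridges beneath narrow peaks, and
  follows narrow valleys.
* **SNV**: per-spectrum zero mean, unit sample (n−1) sd; constant spectra
  raise.
* **Illumination masking**: pixels with relative illumination below 0.40
  (normalized to max 1) are excluded, and the QC report keeps exact
  bookkeeping: retained = total − border − low-illumination.

## Classification

Feature selection, standardization and calibration use training data only.

* **L1-SVM selector** (liblinear, `penalty="l1"`, C = 0.1 by default,
  exposed in config): channels with non-zero weight are kept. On
  high-contrast tissue spectra the solution is very sparse (2–4 channels,
  landing on the 1001/1442/1739 cm⁻¹ contrast bands). Note sklearn's C
  multiplies the *summed* loss, so sparsity at fixed C depends on sample
  size and separability; on non-separable iid-noise features the same C
  is far less sparse.
* **Grid search** evaluates, in deterministic order, 5 linear-SVM, 25
  RBF-SVM and 9 random-forest configurations on the explicit validation
  set; ties resolve to the earliest point in that order (SVMs before RF,
  ascending C, γ, n_estimators, max_samples).
* **Platt scaling**: a sigmoid `P = 1/(1 + exp(A·f + B))` over SVM
  decision values, fitted with the standard smoothed targets
  `(N⁺+1)/(N⁺+2)`, `1/(N⁻+2)` by Nelder–Mead on the cross-entropy, using
  out-of-fold decision values from a seeded stratified 5-fold CV of the
  training set. Reported confidence is `max(P, 1−P) ∈ [0.5, 1]`; it is
  monotone in the distance from the sigmoid midpoint. Random forests use
  the fraction of trees voting for the predicted class instead (bootstrap
  with replacement, `max_samples` as subsample fraction).
* **Metrics**: adipose is the positive class for sensitivity/specificity
  (documented convention; the margin maps color adipose red, muscle blue,
  masked pixels black).
* **Margin localization**: per scan row, the class-transition column is
  the change-point minimizing step-function mismatch; the margin column is
  the median over rows, and the low-confidence width is the mean length of
  the contiguous confidence-<0.90 run around the transition. A
  single-class map reports "no transition" and width 0.
* **Bundles** serialize to JSON (selected channels, standardization,
  hyperparameters, support vectors/dual coefficients or the forest's tree
  arrays, Platt parameters) and reload into an equivalent predictor
  without pickling.

## Photon budget

Per-factor point/line ratios: intensity (38.2/6.1), bundle transmission
(1/0.375), collecting fibers (7 x 0.417), and the collection-NA factor.
The NA factor 1.96 is **taken as an input**: it is not reproducible from
the printed NAs by the obvious solid-angle formula ((0.22/0.159)² = 1.91),
so the calculator defaults to the stated value and offers
`na_ratio=None` to derive the solid-angle alternative. The overall budget
is the product of the four factors (≈ 96 after rounding, whether from raw
or printed-precision factors). The "upgrade" preset (5 W laser over a
400 µm x 10 mm line, collection NA 0.36) is provided as parameters only.

## Numerical and design choices

* Axis conventions: spectral axes ascending; pixels 0-based; cubes indexed
  (scan x, line y, channel).
* The polynomial fit uses a [−1, 1] abscissa for conditioning; batched and
  single-spectrum fits may differ in the last float bits.
* Sub-pixel peak refinement falls back to the integer argmax at spectrum
  edges or on non-positive triples.
* Problem sizes in tests and the acceptance script: study-level checks run
  20 full-size (40 x 42 x 341) simulated studies — enough seeds to expose
  seed-dependence while keeping the whole suite in the minutes range; the
  planted-band-recovery datasets use two 12-line pure scenes per seed
  (~890 training spectra), matching the study's training scale.

## Known limitations

* Single-sample world: one template pair, no inter-subject variability, so
  classifier generalization claims are out of scope.
* The bleed model is one-sided exponential in the scan direction only; real
  spatially offset contributions are 2-D and depend on optical properties.
* The expected retained-spectra count is exact bookkeeping from the masks;
  the half-image training counts (e.g. 741 per class) of a specific real
  acquisition depend on its border/illumination geometry and are not
  reproduced exactly by the default masks.
* No alternative baseline algorithms (wavelet, airPLS, SNIP) — only the
  polynomial + rolling-ball chain, by design.
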