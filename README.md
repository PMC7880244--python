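# ramanmargin

Simulation, preprocessing and classification pipeline for **macroscopic
line-scan Raman imaging of tissue margins**.

Intraoperative margin assessment needs label-free molecular contrast over
centimeter-scale fields of view. A line-scanning Raman imager acquires one
laser line of spectra at a time (here 40 lines x 42 positions x 341
spectral channels covering the 400–1900 cm⁻¹ fingerprint region), producing
a hyperspectral cube in which each pixel holds a full Raman spectrum. This
package is aimed at researchers building or evaluating such systems: it
provides a ground-truth simulator of two-tissue (porcine adipose vs muscle)
margin scenes, the standard spectral preprocessing chain, sparse
classifier development with calibrated confidence maps, and the
photon-budget arithmetic used to compare a line scanner against a
single-point probe.

## The method

**Simulation.** Tissue spectra are sums of Lorentzian bands at the known
porcine positions — muscle carries the 1001 cm⁻¹ phenylalanine breathing
mode; adipose carries strong CH₂ deformation (1442 cm⁻¹) and ester
carbonyl (1739 cm⁻¹) bands and lacks 1001 cm⁻¹ — under an intense smooth
fluorescence background, a multiplicative system response with scratch
artifacts on the intensity standard, signal-proportional shot noise
(adipose SNR > muscle SNR), cosmic-ray spikes, and a one-sided exponential
bleed of adipose signal into near-margin muscle pixels (the spatially
offset, in-depth contribution seen when the scan crosses a margin).

**Preprocessing**, per spectrum *x(λ)*, in order: cosmic-ray elimination
(running-median outlier detection and replacement); Raman-shift calibration
by a monotone cubic spline through the six most prominent acetaminophen
peaks (an ASTM E1840 shift standard); division by the 2-D Gaussian-smoothed
broadband intensity-standard measurement (border spectra rejected);
background removal by a fifth-order polynomial fit followed by a
rolling-ball pass (grayscale opening, ball radius 16 channels); and
standard normal variate (SNV) normalization,
`x → (x − mean(x)) / sd(x)`.

**Classification.** An L1-penalized linear SVM selects the spectral
channels with non-zero weight; features are standardized with training
statistics; a grid search over linear SVM (C ∈ {0.001…10}), RBF SVM
(C, γ ∈ {0.001…10}) and random forest (n_estimators ∈ {100, 200, 300},
max_samples ∈ {0.6, 0.7, 0.8}) — 39 configurations — picks the model with
the best validation accuracy. Class confidences are Platt-scaled sigmoid
probabilities of the SVM decision value (5-fold CV on training data),
yielding margin maps with per-pixel confidence in [0.5, 1.0]; the margin
is localized as the median per-row class-transition column.

**Photon budget.** The point-probe/line-scanner collection ratio is the
product of the intensity, fiber-transmission, collection-NA and
collecting-fiber factors.

## Worked example

```bash
python examples/train_and_map.py
```

prints (seed 1):

```
best model: svm {'kernel': 'linear', 'C': 0.001}
selected Raman bands (1/cm): [1000.  1441.2 1736.8 1741.2]
validation accuracy: 1.000
margin-image accuracy/sensitivity/specificity: 1.000/1.000/1.000
estimated margin column: 20.0 (planted at 20)
mean width of <90%-confidence band: 0.12 px
```

The L1 selector keeps only channels on the real contrast bands (the
phenylalanine band near 1001 cm⁻¹, the CH₂ band near 1442 cm⁻¹ and the
lipid carbonyl near 1739 cm⁻¹); the classifier separates the two tissues
essentially perfectly at the simulated SNR, and the estimated margin
column matches the planted boundary. `examples/simulate_and_preprocess.py`
and `examples/photon_budget.py` demonstrate the other two capabilities.

A command-line interface mirrors the library:

```bash
ramanmargin simulate --out cube.h5 --acetaminophen-out ref.csv --standard-out std.h5
ramanmargin preprocess --cube cube.h5 --acetaminophen ref.csv --standard std.h5 \
    --out processed.h5 --qc qc.json
ramanmargin budget
ramanmargin run --outdir results/ --seed 0   # full study + manifest
```

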