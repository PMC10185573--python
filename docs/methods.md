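# Methods

## The sensing problem

A dual-analyte optode is a two-layer luminescent film that reports pH and
dissolved O₂ at the same spot: a hydrogel top layer carrying a lipophilic
pH indicator (distinct acid/base emission forms), and a polystyrene bottom
layer carrying an O₂-quenched NIR phosphor (emission ≈ 770 nm) together
with an analyte-insensitive reference dye (emission 500–600 nm). Read out
with a hyperspectral camera, every image pixel carries a full emission
spectrum (470–900 nm, 3 nm step → 144 bands).

In isolation each analyte obeys a textbook calibration law:

* pH — Boltzmann sigmoid. The fraction of indicator in its base form is
  `f(pH) = 1 / (1 + 10^((pKa − pH)/s))`, midpoint at the apparent pKa,
  slope `s` in pH units. With `s = 1` the response saturates over roughly
  pKa ± 2, which defines the sensor's dynamic range (pH 5–9 for pKa 7).
* O₂ — simplified Stern–Volmer quenching. The phosphor intensity follows
  `I(pO₂) = I₀ / (1 + K_SV·pO₂)` with `K_SV` in hPa⁻¹; air saturation is
  taken as 195 hPa under the calibration conditions (22.5 °C).

The layers are, however, optically coupled by reabsorption (inner-filter)
effects: part of the acid-form emission overlaps the O₂-layer absorption
(strongest under anoxia, when the phosphor ground-state population is
largest, and under acidic pH, when the acid form dominates), and part of
the reference emission overlaps the base-form absorption. Each analyte's
signal therefore depends on the other analyte, single-analyte fits fail,
and a supervised model that sees the whole spectrum is used instead.

## Forward simulator (`synthspec`)

The simulator is the package's synthetic ground truth. Every emission band
is a unit-height Gaussian `G(λ) = exp(−(λ−c)²/2w²)` scaled by an
amplitude; the noiseless spectrum is

```
S(λ; pH, pO₂) = (1−f)·A_a·(1 − ct_a·g(pO₂))·G_a(λ)        acid form
              + f·A_b·G_b(λ)                               base form
              + A_r·(1 − ct_r·f)·G_r(λ)                    reference dye
              + I₀/(1 + K_SV·pO₂)·G_o(λ)                   O₂ phosphor
```

with `f = f(pH)` the Boltzmann fraction and `g(pO₂) = 1/(1+K_SV·pO₂)` the
O₂-layer absorption saturation — reabsorption of the acid emission is
strongest under anoxia, mirroring the physical coupling described above.

Default parameters (chosen once; all configurable):

| parameter | default | why |
|---|---|---|
| grid | 470–900 nm, 3 nm step (144 bands) | camera acquisition axis |
| pKa | 7.0 | midpoint of the pH 5–9 dynamic range |
| Boltzmann slope | 1.0 pH | saturation over pKa ± 2 |
| acid band | 490 nm, σ 25 nm, A 1.0 | acid form emits 400–550 nm |
| base band | 548 nm, σ 30 nm, A solved | see isosbestic note below |
| reference band | 535 nm, σ 28 nm, A 0.6 | reference dye emits 500–600 nm |
| O₂ band | 770 nm, σ 20 nm, I₀ 1.0 | NIR phosphor |
| K_SV | 0.01 hPa⁻¹ | ≈ ⅓ of I₀ left at air saturation — typical Pt-porphyrin behaviour |
| ct_a (acid→O₂-layer) | 0.30 | free parameter, set so single-analyte fits visibly fail |
| ct_r (ref→base-form) | 0.15 | same; weaker than the acid path |
| noise_sd | 0.02 a.u. | ≈ 2 % of the strongest band; camera shot/read noise at short integration |

Isosbestic point. The pH-dependent part of the spectrum at fixed pO₂ is
`f·[A_b G_b − α G_a − A_r ct_r G_r]` with `α = A_a(1 − ct_a·g)`; spectra
for all pH values at one pO₂ therefore share an exact common crossing
where the bracket vanishes. The default base amplitude
(A_b ≈ 0.33906) is the closed-form solution that places this crossing at
530 nm under anoxia; with the default cross-talk it drifts to ≈ 533 nm at
air saturation, within the ± 6 nm (two-band) tolerance asserted by the
tests. Setting both cross-talk factors to zero reduces the model to an
exact sum of four independent bands, which the tests compare against the
closed-form Boltzmann/Stern–Volmer factors at 1e−9 relative error.

Noise is additive i.i.d. Gaussian per band, clipped at zero, with no
wavelength correlation — the simplest model consistent with the
noise-mitigation role of RoI aggregation. Clipping makes the effective
noise slightly sub-Gaussian where the signal is near zero; the noise-sd
recovery test therefore checks a strong band.

The imbalanced sampling preset gives anoxic and air-saturated O₂ points a
6× sample budget, emulating real calibration campaigns that dwell at the
two bracketing O₂ end points.

What the simulator does not model: radiative-transfer-accurate layer
optics, FRET/PET kinetics, excitation-side spectra, temperature
dependence, spatially correlated noise, bleaching/leaching drift. Passing
tests therefore demonstrate that the pipeline recovers analytes under the
stated spectral-coupling and noise model, not that it handles every
artefact of real instrument data.

## Data preparation (`prep`)

* RoI tiling: non-overlapping 5×5-pixel tiles over the (optionally
  restricted) frame; partial edge tiles are discarded. A full 1088×2048
  frame yields 217·409 = 88 753 tiles.
* Outlier cleaning: per band within each RoI, a Tukey fence
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with linear-interpolation quantiles,
  applied exactly once (the fence always derives from the original 25
  values). The per-band axis is a documented choice; the alternative
  (cleaning on a whole-spectrum summary statistic) is configurable at the
  call level by composing `iqr_clean` manually.
* Aggregation: per-band median of the surviving pixels.
* Balancing: groups are calibration points keyed by (pH rounded to 0.1,
  pO₂ rounded to 1 hPa); the target is the median per-group count
  (floored when half-integral). Oversized groups are partitioned in
  stable stored order into `target` near-equal chunks (`array_split`
  sizes ⌈n/t⌉/⌊n/t⌋) and each chunk replaced by its mean spectrum and
  mean labels. No shuffle and no seed: balancing is deterministic.
* Split: uniformly random disjoint 80:20 train/validation partition,
  |train| = round(0.8·N), seeded.

## The cascade model (`cascade`)

Three XGBoost regressors on absolute (not ratiometric) intensities:

1. pH ← spectrum,
2. pO₂ ← spectrum ⊕ predicted pH,
3. pO₂ ← spectrum ⊕ predicted pH ⊕ layer-2 pO₂ — one stacked
   refinement pass.

pH is predicted first because O₂ quenching and the cross-talk terms
perturb the spectrum more strongly than pH shifts do; conditioning the O₂
layers on pH lets them compensate the pH-dependent reabsorption.

Conditioning features during training are out-of-fold predictions from an
internal 5-fold split (default), so layers 2–3 train on features with
realistic, not memorised, error; `conditioning="label"` reproduces the
simpler label-conditioning variant. Tuned layer configurations:
pH (n_estimators 250, min_child_weight 3, max_depth 9, learning_rate
0.05); both O₂ layers share (250, 5, 7, 0.05). Squared-error objective,
`hist` tree method, single-threaded with fixed seeds for bit-identical
reruns.

Predictions outside the pH 5–9 dynamic range are flagged invalid, never
clipped or interpolated: the sensing chemistry saturates there, so a
numeric value would be physically meaningless even when the regressor
emits one.

Model selection surveys nine families (linear, lasso, ridge, logistic,
random forest, SVR, k-NN, decision tree, XGBoost), each fitted
independently per analyte; failures become NaN report cells. "Logistic
regression" on a continuous target is implemented as multinomial
classification on integer-rounded labels scored as regression — it is
retained as a diagnostic row and expected to perform poorly. HPO
enumerates a grid or draws a seeded random subset; the best configuration
minimises validation MAE with ties broken by validation RMSE, then
first-seen order.

Serialization is a directory: a JSON manifest (wavelength axis, layer
configurations, conditioning mode) plus one booster-JSON file per layer,
deliberately independent of the sklearn wrapper state.

## Metrics and validation (`evalx`)

MAE = Σ|yᵢ−xᵢ|/N and RMSE = √(Σ(yᵢ−xᵢ)²/N); RMSE ≥ MAE always, with
equality iff all absolute residuals are equal. k-fold cross-validation
(default k = 10) randomly partitions the table into near-equal folds;
every row is validated exactly once by a model trained without it.
Aggregation is the unweighted mean ± sd over folds. The report carries
pH, first-pass O₂ (layer 2) and refined O₂ (layer 3) separately so the
refinement benefit is visible.

## Chemical images (`chemimage`)

`predict_image` is defined as the flattened batch prediction reshaped —
a test asserts bit-identity — so no spatial coupling can sneak in. An
optional median filter exists behind a flag and is off by default.
Invalid pixels are NaN in numeric exports (float64 TIFF, lossless) and a
dedicated palette colour in 8-bit PNG previews whose colourbar limits
(default pH 5–9, O₂ 0–195 hPa) are recorded in `metadata.json`.

## Problem sizes used in the shipped study

Chosen once as a desk-scale study a workstation reproduces in minutes:

* Parameter recovery: pH 4–11 step 0.5 × pO₂ 0–195 hPa step 15, 25
  samples/point (5 250 rows), 80:20 split; run noiseless and at the
  default noise.
* Cross-validated refinement: pH 4–11 step 1 × 5 O₂ points with the
  imbalanced preset (960 rows), balanced to 320 rows, 10-fold CV.
* Gradient scene: 24 × 60 px, pH ramp 5→9 at fixed 50 hPa.

The calibration grid deliberately extends past the dynamic range (pH 4
and 9.5–11) because real calibrations do; pH accuracy collapses outside
5–9 where the sigmoid saturates, which is exactly why those predictions
are masked invalid. The reproduction script therefore reports the noisy
held-out pH MAE both over the full grid and restricted to the pH 5–9
dynamic range — the former is dominated by the saturated extremes, the
latter reflects the accuracy of predictions the sensor actually asserts
as valid.

## Numerical choices and edge cases

* Quantiles: linear interpolation between order statistics (NumPy
  default), matching the brute-force oracles.
* IQR = 0 (all-equal data): values sit on the fence boundary and are
  retained.
* Fewer than 4 values per cleaning group: passed through with a warning.
* Balancing target with an even group count: floor of the median.
* Single-valued training target: the layer degenerates to a constant
  predictor; a warning is emitted rather than an error.
* Split rounding: |train| = round(ratio·N) exactly; N = 10 at 0.8 gives
  8/2.
* HPO ties: validation MAE, then validation RMSE, then insertion order.
* All RNGs are `numpy.random.default_rng` seeded explicitly; XGBoost runs
  single-threaded (`n_jobs=1`) so repeated runs are bit-identical.

## Known limitations

* The cross-talk coefficients are plausibility-chosen, not fitted to
  measured dye spectra; absolute error magnitudes on synthetic data do
  not transfer to any particular real optode.
* The balancing partition ("average larger groups") is one deterministic
  reading of group-averaging; other partitions are equally admissible and
  would change balanced counts on real data.
* Layer-3 refinement is a single stacked pass; iterating further is
  possible but untested.
* The logistic-regression row of the selection report is diagnostic only.
* ENVI support covers BSQ interleave, little-endian, the numeric dtypes
  the camera ecosystem emits (u8/i16/i32/u16/f32/f64); BIL/BIP variants
  are out of scope.
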