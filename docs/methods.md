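# Methods

`nirmoist` implements a complete short-wave NIR (900–1650 nm) calibration
workflow for predicting the moisture content of dried seaweed (nori) sheets
from diffuse-reflectance absorbance spectra: synthetic data generation,
derivative preprocessing, representative train/test partitioning,
genetic-algorithm wavelength selection with a PLS criterion, three regressor
families, Gaussian-process prediction intervals, and point/interval metrics.
This note records the models, the defaults and why, the numerical choices,
and the known limitations.

## Synthetic spectra model

Real spectra for this product class are not publicly deposited, so the
package ships a generator that emulates their salient structure. A clean
spectrum is a sum of Gaussian absorption bands whose amplitudes couple
linearly to moisture mass fraction m/100:

    A_i(λ) = (1 + a_i) · Σ_b [amp_b + c_b · m_i/100] · exp(−(λ−λ_b)²/(2w_b²)) + b_i + ε_iλ

with per-sample multiplicative scatter a_i ~ N(0, 0.05²), additive offset
b_i ~ N(0, 0.02²), and channel noise ε ~ N(0, 0.002²) in absorbance units —
magnitudes typical of handheld diffuse-reflectance instruments. The default
band set encodes the chemistry that matters at these wavelengths:

| band | centre (nm) | width (nm) | base amp | moisture coupling |
|---|---|---|---|---|
| O–H first overtone (water) | 1430 | 45 | 0.25 | 2.2 |
| C–H second overtone (carbohydrate) | 1180 | 35 | 0.28 | 0 |
| polysaccharide–water interaction | 1365 | 18 | 0.08 | 0.5 |

Amplitudes were chosen once so that the water band is the global spectrum
maximum across the whole moisture range (as observed in real dried-seaweed
spectra) and the carbohydrate band is a strong moisture-independent
confounder; the interaction band is kept narrow so it remains spectrally
distinct from the water band.

Moisture is drawn from a normal distribution truncated to
[4.37, 14.84] % with target mean 10.18 % and SD 2.78 % — the descriptive
statistics of a commercial dried-nori calibration set. Because asymmetric
truncation shifts the mean of a truncated normal, the location parameter is
re-centred by root finding so that the *truncated* distribution's mean
equals the configured mean; `moisture_mean` therefore really is the
expected value of the draw (the realised SD is somewhat below the nominal
2.78 because of the truncation).

The default grid is 125 channels over 900–1650 nm. The acquisition
geometry (3.0 nm sampling) would give 251 points; 125 matches the model
input dimension used throughout, and both are supported via `n_channels`.

One seed drives three independent sub-streams (moisture, scatter, noise)
via spawned `SeedSequence`s, so any stage can be regenerated in isolation
and the whole generator is bit-reproducible.

What the generator does **not** emulate: instrument line-shape and
dark/white-reference drift, temperature-dependent band shifts, the
nonlinear weakening/shifting of the water band at very low moisture, and
inter-batch chemistry differences. Passing tests on this generator
demonstrate that the pipeline's algorithms behave correctly under a known
ground truth; they do not certify accuracy figures on real spectra.

## Preprocessing

Savitzky–Golay smoothing and the first derivative are applied in a single
least-squares convolution (scipy's `savgol_filter` with `deriv=1`),
returning absorbance per nm. The derivative removes additive baseline
offsets exactly and attenuates multiplicative scatter; the polynomial fit
suppresses noise. Defaults `window_length=11`, `polyorder=2` are common
chemometric practice; both are exposed. Edges use the re-fitted boundary
polynomial (`mode="interp"`) so output shape equals input shape. Uniform
grids are required (relative tolerance 1e-6); the derivative is applied
*before* partitioning, so SPXY operates on preprocessed spectra.

## SPXY / Kennard–Stone partitioning

Both partitioners grow the training set by max–min selection, seeded with
the most distant pair. Kennard–Stone uses the Euclidean spectral distance;
SPXY uses the joint distance dx/max dx + |Δy|/max dy so the training set is
representative in spectral and chemical space simultaneously. Ties break
toward the lowest index (the literature is silent; this makes the split
fully deterministic). If a distance term is degenerate (max 0) it is
dropped with a warning. The default 300/80 split mirrors the study design
the package targets; any `n_train` is accepted. Whether the test-set
response range falls inside the training range is *reported* (diagnostics),
not asserted, since max–min selection does not guarantee it.

## GA–PLS wavelength selection

Binary chromosomes are channel masks. Fitness is the negative k-fold
cross-validated MSE of a PLS regression restricted to the masked channels
(CV rather than a single validation split, to reduce selection variance).
Masks with fewer than `min_selected` active channels score −∞ rather than
raising, so the GA can score any chromosome; entirely infeasible offspring
are repaired by activating random bits. Operators: tournament selection
(size 3), uniform crossover at rate 0.8, per-bit mutation at 0.02, elitism
2. The initial population has expected density 0.3 plus the all-ones
chromosome, which guarantees the returned subset never scores worse than
the full spectrum on the training CV criterion. Defaults (population 100,
50 generations, 8 PLS components, 5 folds) are standard GA–PLS practice;
the desk-scale benchmark and tests use smaller populations/generations
because the planted-signal structure is recovered long before the defaults
are exhausted. The number of selected channels is data-dependent and not
enforced.

Channel importance is the PLS regression coefficient on *standardised*
predictors, so magnitudes are comparable across channels with different
variances. Component counts are reduced automatically (with a warning) when
they exceed the data rank. PLS itself is scikit-learn's `PLSRegression`
with mean-centring only (`scale=False`); standardisation where needed is
explicit.

## Regressors

All three accept `(n_samples, n_channels)` matrices — full spectrum or any
selected subset — and a moisture vector. Moisture enters models on the
**fraction** scale (percent/100) by default, so errors are on the scale on
which results in this field are typically tabulated; reports can carry
both scales.

* **Gradient boosting** (`xgboost`): squared-error objective with the
  regularised complexity penalty γT + ½λ‖ω‖²; λ and γ are passed through
  as `reg_lambda`/`gamma`. Defaults: 400 trees, depth 6, learning rate
  0.05, λ=1, γ=0, single-threaded exact tree method for bit determinism.
* **1-D CNN**: conv(64, 7-tap) → maxpool → conv(128, 3-tap) → maxpool →
  conv(256, 3-tap) → flatten → dense(64) → dense(1), ReLU throughout,
  trained with Adam (lr 0.001) on MSE for exactly `epochs` epochs — the
  epoch count is the stopping criterion, no early stopping. Default 800
  epochs.
* **1-D ResNet-18**: 7-tap stride-2 stem convolution + batch norm + 3-tap
  stride-2 max pool, then four stages of two basic blocks (two 3-tap
  convolutions each — 16 in total), widths 64/128/256/512, identity
  shortcuts within a stage and 1-tap projection shortcuts at stage entries,
  global average pooling and a linear head. Adam, lr 0.0001, default 1200
  epochs.

The network layers (convolution, pooling, batch norm, dense, residual
blocks, Adam) are a self-contained numpy implementation with manual
backpropagation (`nirmoist._nn`), channels-last so convolutions reduce to
a few GEMMs per kernel tap, float32 throughout. Inputs are standardised
per channel and targets standardised internally; the output head is
zero-initialised, so an untrained network predicts the training mean.
Because the implementation is pure numpy, training is bit-deterministic
for a fixed seed; the documented reproducibility tolerance for network
predictions is 1e-4.

Unstated architecture details were fixed once as conventional choices:
kernel sizes 7 (stem) / 3 (elsewhere), ReLU, Adam, batch 32, no batch norm
in the plain CNN, batch norm inside residual blocks.

## Prediction intervals

A 1-D GP regression is fitted from a model's point predictions to the
measured values, kernel σ_f²·Matern(ν=5/2) + white noise σ_n², with
hyperparameters set by marginal-likelihood maximisation (two random
restarts by default; fits on thousands of points use a single run). The
predictive variance *includes* σ_n² — these are prediction intervals for
observations, not confidence intervals for the latent mean — and the 95 %
bounds are μ* ± 1.96·σ*, with σ* the predictive **standard deviation**
(a variance in the bracket would not scale correctly). The calibration is
fitted on training-set (prediction, actual) pairs and applied to test-set
predictions; fitting on pooled train+test pairs would leak test targets
into the interval and is available only as an explicit opt-in
(`include_test_in_gpr_fit`) for protocol comparisons.

A consequence worth understanding: when a model interpolates its training
data (boosted trees and generously sized networks routinely do), the
training-pair residuals understate test-time error, the fitted σ_n is
correspondingly small, and test-set coverage falls well below the nominal
95 %. That is a property of the strict protocol, not a defect of the GP:
under the pooled protocol coverage is near-nominal but optimistic because
the intervals have seen the test targets. The interval machinery itself is
validated separately on well-specified simulations, where the 95 %
intervals cover 93–97 % of held-out observations. GP inputs are the
1-D prediction values alone, not the spectra. Degenerate calibrations
(zero spread) fall back to a fixed kernel with a σ_n² floor of 1e-8, with
a warning.

## Metrics

* R² uses the conventional denominator Σ(y−ȳ_actual)²; a variant centred
  on the mean of *predictions* would rate any constant-shifted predictor
  perfectly and is not used.
* RMSEP divides by n−1 (the convention in this line of work) rather than n.
* RPD is reported in two conventions, `1/sqrt(1−R²)` and SD(actual)/RMSEP,
  and reports label which is used: published RPD values in this area do not
  always match either convention, so both are surfaced rather than
  reconciled silently.
* PICP uses strict inequalities: a value exactly on a bound counts as
  uncovered.
* PINAW normalises the mean absolute interval width by the observed
  response range of the evaluated set (test-set range).
* CWC = PICP/PINAW, higher is better.
* Percent changes support three conventions (increase vs old, decrease vs
  old, reduction vs new) because comparative statements in this field mix
  them; every reported change is labelled.

## Orchestration and problem sizes

`run_experiment` executes generate/load → derivative → split → GA selection
→ {XGB, CNN, ResNet} × {full, selected} → GP intervals → metric grid, and
writes split/selection JSON, per-run prediction and interval CSVs, the
six-row report CSV, and a manifest with the seed, per-stage wall-clock and
a config hash. One run seed fans out to every stochastic stage.

Desk-scale defaults used by the test suite and the acceptance script:
380 samples × 125 channels with a 300/80 SPXY split; GA population 30 × 12
generations; network epochs 100 (CNN) and 150 (ResNet). These sizes were
chosen once as the package's benchmark scale — the networks on the
synthetic task converge well before the full 800/1200 epochs, which remain
the config defaults.

## Known limitations

* The synthetic generator is a stylised additive-band model; see above for
  the instrument effects it omits. Accuracy numbers on it do not transfer
  to real spectra.
* The GA fitness is a training-CV criterion; selected subsets are not
  guaranteed optimal for an independent test set.
* The GP calibration is homoscedastic in the prediction coordinate;
  moisture-dependent error structure would need a heteroscedastic GP.
* SPXY cost is O(n²) memory in the distance matrices; fine for thousands
  of samples, not for hundreds of thousands.
* Networks are CPU-only by design; the numpy implementation favours
  determinism and portability over speed.
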