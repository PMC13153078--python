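# Methods

## Scope and intent

`ricelpn` implements an LPN-estimation analysis as a seeded, testable
pipeline. Because no field campaign is bundled, a synthetic-data module
generates inputs with the statistical structure the analysis assumes; every
downstream stage (preprocessing, indices, selection, augmentation, models,
explanation) is written to operate identically on real per-plot spectra
supplied as CSV.

## Synthetic campaign

**Design.** Full factorial: nitrogen rates (0, 37.5, 75, 112.5, 150,
187.5 kg/hm²) × 5 replicate plots = 30 plots; 5 leaf subsamples per plot
give 150 samples.

**LPN response.** `LPN(r) = l0 + (lmax − l0)·r/(k_half + r) + ε`,
`ε ~ N(0, σ²)`, clipped at 0. A saturating Michaelis–Menten form is the
simplest monotone-with-plateau response; alternatives can be passed as
different `LpnModelParams`. Defaults `l0 = 1.2`, `lmax = 4.0`,
`k_half = 75` (% dry mass and kg/hm²) place realized LPN in roughly
1.2–3.2 % dry mass, a realistic leaf-protein-nitrogen range for rice and
one on which an RMSE near 0.2 % is a meaningful error. Subsample noise
σ = 0.15 % reflects within-plot heterogeneity plus wet-lab error. An
optional plot-level random effect (`plot_sigma`) is off by default.

**Spectra.** 224 evenly spaced band centers over 400–1000 nm (the real
imager's exact centers are instrument-specific; nearest-band lookup absorbs
the difference). The chlorophyll proxy `c = clamp(LPN/4.0, 0, 1)` drives a
logistic red edge `S(λ) = 1/(1 + exp(−(λ − λre)/10))` with
`λre = 700 + 15·c` nm, blending a visible regime (0.05 floor, +0.06 green
peak at 550 nm damped by `c`, −0.035·c red trough at 670 nm, floored at
0.01) into a NIR plateau `0.40 + 0.10·c`. Multiplicative band noise
`N(1, 0.02²)`; reflectance clipped to [0, 1]. All constants live in
`SpectrumShapeParams`.

**What this emulates and what it does not.** The emulator reproduces the
monotone red-edge/NIR signature of canopy nitrogen (NDVI and MTCI are
provably nondecreasing in LPN with noise off) and sensor noise. It contains
no radiative-transfer physics, no soil/shadow mixtures, no water-absorption
features, and its band-to-band noise is independent — so passing tests
demonstrate the *pipeline's* correctness and the method's behavior under a
controlled signal, not field-level accuracy. Headline accuracies on the
synthetic campaign are higher than one should expect on field data.

## Preprocessing

Gaussian denoising uses a discrete kernel with σ in band units (default 1),
truncation at 4σ, unit normalization and reflect padding
(`scipy.ndimage.gaussian_filter1d`). Smoothing is applied to ROI-mean
spectra (whether one smooths pixels or means is immaterial here: the two
orders commute for a linear filter, and the suite asserts it). Wavelength
resolution uses nearest-center matching, ties toward the lower wavelength;
interpolation is deliberately avoided so selected band features keep actual
band-center names (e.g. `B_775.60`).

## Index registry

The 20 registered formulas are kept exactly as printed in the source
formulary, including two entries that deviate from common literature
variants: OSAVI with the 1.16 factor in the numerator and +0.16 in the
denominator, and MSR as `(R800/R760 − 1)/√(R800/R670 + 1)` (the canonical
R670 variant is available per call). DCNI's unparenthesized chain of
divisions is read left-associatively:
`((R720 − R700)/(R700 − R670))/(R700 − R670 + 0.03)`. A zero denominator
yields NaN; assembly either drops such samples (default, warned) or
mean-imputes.

## Selection

Entry thresholds: gain-based importance fraction FI > 0.02 from a
gradient-boosted tree ensemble (200 trees, depth 4, learning rate 0.1,
fixed seed — these hyperparameters are this package's choices) or
|Pearson r| > 0.75 with LPN; both criteria are applied to all 244 features.
The two criteria's picks are merged by union, then pruned: repeatedly take
the surviving pair with the highest inter-feature |r| ≥ 0.8 (ties by name)
and drop one member — keep the stronger |r| with the target; if the two
target correlations differ by less than 0.05 ("comparable"), keep the
higher FI; a residual tie falls to alphabetical order. Every drop is
logged with the rule that fired. A published-variable preset
(`paper_feature_preset`: bands near 775.6, 444.89, 553.58, 639.48 nm plus
PSND, MTCI, DCNI) lets the modeling stages run with a fixed external
variable set.

## WGAN augmentation

Generator 16→64→64→d and critic d→64→64→1, leaky-ReLU (0.2) hidden
layers — network shapes are this package's defaults, exposed in
`WganConfig`. Training: five critic steps per generator step; the critic
ascends `mean D(x) − mean D(G(z))` (implemented by minimizing the
negation — the direction in which the real-minus-fake score estimates the
Wasserstein distance), the generator descends `−mean D(G(z))`; all critic
parameters are clipped to ±0.01 after each step (the weight-clipping route
to the Lipschitz constraint); Adam(β₁ = 0, β₂ = 0.9), learning rates 1e-4
(generator) and 2e-4 (critic), batch 16, 200 epochs. Rows (selected
features **and** LPN jointly — the augmented regression fit needs both) are
z-scored on training statistics and de-standardized on generation;
generated rows are clipped per column to the training range ± half the
range to exclude physically absurd values (configurable off). Networks and
backpropagation are plain numpy; at this scale an autodiff framework adds
nothing. Diagnostics per feature: means, s.d.s, two-sample KS, and the
empirical 1-D Wasserstein distance (integral of |ΔECDF|).

## Models and evaluation

Split 4:1 (120/30) by seeded permutation **before** selection and
augmentation; the pipeline asserts by row identity that no test sample
reaches a training-side stage. MLR is closed-form least squares with a
pivoted-QR diagnosis of rank deficiency; PLSR is NIPALS (scikit-learn),
default 3 components; SVR uses an RBF kernel, C = 10, ε = 0.1 on z-scored
features; KNN uses k = 5, uniform weights, Euclidean distance on z-scored
features (k unpublished upstream; 5 is the conventional default). Metrics:
R² = 1 − SS_res/SS_tot and RMSE in % dry mass on the held-out partition.
Augmentation effect is reported both as relative improvement
(R²_aug − R²_orig)/R²_orig × 100 (primary) and absolute ΔR² — the relative
reading keeps an improved R² below 1 for any baseline, so it is the
checkable one.

## Shapley explanation

Exact enumeration over all 2^|M| coalitions with the interventional value
function: v(S) is the model's mean prediction over background rows with the
instance's values substituted on S. Efficiency (φ₀ + Σφᵢ equals the
prediction) is then structural and asserted at 1e-8 on every run; the test
suite also checks equivalence with an independent permutation-average
implementation at 1e-10 and the closed form φᵢ = βᵢ(xᵢ − x̄_bg) for linear
models. The background defaults to the training partition, subsampled to
100 rows with a fixed seed; explained instances default to the test
partition. Exact enumeration is limited to 15 features; the pipeline caps
the explained set at the 10 features most correlated with the target
(screened sets here are far smaller). Ranking is by mean |φ|, ties
alphabetical; the sample heatmap order comes from average-linkage
agglomerative clustering of per-sample φ vectors under Euclidean distance.

## Numerical and degenerate-input conventions

- Constant features get r = 0 rather than an error during screening;
  a constant target aborts selection with a warning.
- Zero-variance columns standardize with σ replaced by 1.
- KNN distance ties resolve by training-row order; nearest-band ties to the
  lower wavelength; ranking ties alphabetical — all deterministic.
- Every stochastic stage draws from `numpy.random.default_rng` seeded from
  one master seed; re-running a configuration reproduces every output file
  byte-for-byte.

## Problem sizes

The default configuration (150 samples, 224 bands, 1000 synthetic rows,
200 WGAN epochs) runs the whole pipeline in seconds on one CPU, so tests
and the acceptance script use it unreduced; only a few unit tests shorten
the WGAN schedule where training quality is not under test.

## Known limitations

- The spectral emulator's simplicity makes the regression task easier than
  field conditions; absolute R² values are not comparable to field studies.
- Weight clipping is the only Lipschitz mechanism implemented; a gradient
  penalty is a natural extension (the Adam β choices match either recipe).
- No conditional (per-treatment) generation, no uncertainty intervals, no
  spatial mapping of predictions.
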