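# Methods

This note records the models, conventions and numerical choices behind
`mozzage`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and conventions

A spectral dataset is a matrix of unitless absorbance values on a shared
uniform wavelength grid (canonical reference: 350–2500 nm at 1 nm, the range
of ASD-type field spectrometers; the loader infers the actual step from the
file header rather than assuming it), with one metadata row per mosquito:
study label, species, sex, preservation method, true age in days. Each
spectrum is assumed to already be the average of repeated instrument scans.
Age-group summary tables use the left-open/right-closed convention
≤5, (5,10], (10,15], (15,20], >20 days.

Datasets are split 70/30 into training and test material, and the training
part again 70/30 into an inner training set and a validation set — i.e.
fractions (0.49, 0.21, 0.30) of the whole. The test size is rounded to the
nearest integer, the inner-train size floored, and the validation set takes
the remainder. Splits are stratified by age quintile by default so every
partition spans the age range; without this, a validation set can miss old
ages entirely and leave the bias-correction fit unsupported there. Base PLS
models see only inner-train rows; the stacker and bias corrector see only
validation rows; test rows are never touched during fitting (the suite
verifies this by corrupting test-row spectra and checking the fit is
unchanged).

## Individual age prediction (iPLS)

**PLS core.** Single-response PLS with mean-centred columns; unit-variance
scaling is off by default (classical chemometric practice for absorbance
spectra — the original analyses in this domain never mention scaling), but a
flag exists. Implementation rides on scikit-learn's `PLSRegression`. Because
the score deflation is sequential, a model fitted with k_max components
yields every smaller model exactly by truncating the rotation/loading
matrices; bootstrap cross-validation exploits this to score all component
counts with one fit per bootstrap.

**Component selection.** 25 bootstrap repetitions (configurable): each draws
a with-replacement sample of the training rows, the out-of-bag rows form the
validation fold, and the component count minimising mean out-of-bag RMSE is
chosen, with ties — including numerical ties on noiseless data — broken
toward fewer components. Caps: 20 components for interval models, 40 for the
wide-window model. A constant response returns an intercept-only model;
all-constant spectra are a degenerate-input error.

**Windows.** Interval presets: Anopheles [350–708], [709–1066], [1067–1424]
nm; Aedes [709–1066], [1067–1424] nm; both supplemented by a wide [350–1850]
nm model, which helps for older mosquitoes. A transparent grid search over
equal-width candidate windows (default 358 nm, mirroring the preset widths)
is provided as the search path; candidates are scored by the same bootstrap
CV and the best k kept in wavelength order.

**Stacking.** Base-model predictions on the validation set are combined by
an additive penalized-spline model (one cubic smooth per base predictor).
The smoother is a P-spline: cubic B-spline bases (default 8 basis functions
per term, knots at quantiles) with a second-difference coefficient penalty,
penalty weight shared across terms and chosen by generalized cross-
validation over a log-spaced grid, solved by direct penalized least squares.
This construction was chosen over the installed GAM implementations because
it behaves correctly at the range edges and is robust to noiseless inputs,
both of which the test suite exercises. Inputs outside the fitted range are
clamped to it.

**Bias correction.** Naive pipelines over-predict young and under-predict
old ages — partly regression attenuation under measurement noise, amplified
by the age imbalance of calibration datasets (all the published ones have
more young than old mosquitoes). The corrector fits the same P-spline to
true age versus stacked prediction on the validation set, evaluates it on a
dense grid, and makes it monotone non-decreasing by isotonic regression (a
non-monotone age map is uninterpretable). Beyond the fitted range it
extrapolates linearly with the edge slopes; corrected ages are floored at 0
days and not capped above. Constant raw predictions fall back to the
identity map with a warning. One statistical caveat, verified in the suite:
conditional-mean calibration is unbiased given the *prediction*; per bin of
*true* age, residual shrinkage bias remains at the range edges when the raw
predictor is very noisy.

The "standard" comparison baseline is a single full-spectrum PLS model with
the same bootstrap CV and no stacking or bias correction — the documented
core of classical NIRS age-grading software.

## Accuracy versus calibration size

Test RMSE is studied as a function of training-set size by holding the test
partition fixed and, for each size, repeatedly subsampling the training pool
without replacement, refitting, and scoring. Because individual prediction
error is dominated by sampling variation in the calibration data, the
central limit theorem motivates the square-root law

    RMSE(n) = a + b / sqrt(n),

with asymptote `a` (days) and scale `b` (days·√mosquitoes), fitted to the
per-size median RMSEs by Gaussian maximum likelihood — for this linear-in-
parameters model, least squares on the regressor 1/√n, with non-negativity
enforced. The reference coefficients shipped with the package,
a = 0.44, b = 34.81, come from a published learning-curve analysis of a
large (n = 871) single-study *An. arabiensis* calibration dataset; they
imply ~2.0 days RMSE at n = 500 and strong diminishing returns beyond
n ≈ 800. Learning-curve replicates that subsample below ~100 rows cannot
support the default spline basis; scaled-down experiments pass a reduced
basis (df 3–4, lower row minimum) explicitly, as the examples do.

## The surrogate measurement model

Population simulations need p(predicted age | true age), not spectra. The
surrogate is a heteroscedastic linear model

    predicted ~ Normal(α + β·age, (σ₀ + σ₁·age)²),

the simplest form consistent with an approximately linear calibration and a
prediction spread that widens with age. An unbiased pipeline gives α ≈ 0,
β ≈ 1. Priors are weakly informative and overridable: α ~ N(0, 5²) days,
β ~ N(1, 1²), σ₀, σ₁ ~ Half-Normal(2.5). Three fitting modes: `map`
(deterministic posterior mode, used by tests), `laplace` (MAP plus Gaussian
posterior approximation, 2000 draws — the default; per-parameter 95%
interval coverage is verified by simulation in the suite), and `mcmc`
(affine-invariant ensemble sampler via emcee; acceptance fraction recorded).
σ₀ is bounded below at 10⁻⁶ and σ₁ at 0, so the noise scale is positive on
any age range.

Simulated predictions are floored at 0 days by default (a negative predicted
age is not reportable); `floor_at_zero=False` gives strictly mean-zero
error. An unbiased homoscedastic surrogate can also be derived directly from
a calibration size via the square-root law: α = 0, β = 1, σ = a + b/√n.

## Population inference

Under constant recruitment and age-independent mortality the stationary age
distribution is exponential and the mean-age MLE is the sample mean.
Senescence and trap bias are out of scope by design.

**Intervals.** 95% intervals are Monte-Carlo percentile intervals of the
estimator. The default resamples the observed readings (nonparametric
bootstrap; degenerate data honestly yields a zero-width interval); a
parametric mode redraws exponential populations at the estimated mean,
optionally pushed through a surrogate, matching the simulation framing used
for survey design.

**Uncertainty decomposition.** Paired two-arm Monte Carlo: each replicate
draws an exponential sample of the survey size; the sampling-only arm
averages the true ages, the total arm averages surrogate-noised versions of
the *same* draws (so a zero-noise surrogate gives a share of exactly 0).
The measurement (NIRS) share is (total width − sampling width)/total width
of the 95% percentile intervals; a variance-ratio alternative is provided.
Measurement noise is plain additive Gaussian here — flooring noised ages at
zero clips the noise arm's spread and adds upward mean bias at young
population ages, so flooring is off by default in the decomposition and
power analyses (available as a flag, with a warning when its mean bias
exceeds 0.05 days).

**Power.** The minimum per-group sample size to distinguish two populations
searches a grid of n; at each n the 95% Monte-Carlo sampling band of each
population's mean-age estimator (noise included) is computed, and the
populations count as distinguishable when the bands separate — the criterion
one applies when reading credible-interval fans off a survey-design figure.
A two-sample z-test power criterion is available instead; it is stricter
(per-replicate separation) and returns larger n. Equal means return `None`
("not achievable"). The proportion of old (≥7 days) mosquitoes is reported
for comparison with the traditional young/old dichotomy; unlike the mean,
its bias under measurement error grows with the error scale, which is the
argument for preferring mean age in monitoring.

## Synthetic data generator

Each synthetic mosquito's spectrum is

    baseline(λ) + (age + η)·S(λ) + study effects + artifacts + noise,

with: a smooth baseline of three broad Gaussian bumps; an age-signal profile
S confined to the preset intervals (raised-cosine windows, linear in age by
default); biological age jitter η ~ N(0, 0.44²) days, making same-age
mosquitoes biochemically different and setting the irreducible individual-
error floor at the asymptote of the reference square-root law; per-study
additive offsets and multiplicative gains plus study-specific smooth
artifact shapes (so cross-study transfer fails, as observed in real
multi-study collections); 60 per-mosquito smooth Gaussian artifacts
(amplitude SD 0.025) representing probe positioning and scattering; and
white instrument noise (SD 0.012, ×4 above 1850 nm where field-instrument
detectors are noisy). The artifact and noise scales were fixed once by
matching the pipeline's error decay to the reference square-root law at
three calibration sizes; the emergent decay is flatter than the reference
law (a higher floor, a smaller slope), which is the main known gap between
the stand-in and real spectra.

Ages come from an explicit list, an exponential mean, or per-bin counts
(integer ages uniform within bins, the last bin extending five days past its
edge). `generate_reference_dataset` reproduces the exact per-study
composition of the published 12-study, 4549-mosquito database (species, sex,
preservation, age-group counts — e.g. its largest study has 871 mosquitoes)
with synthetic spectra.

**What passing tests show — and don't.** On synthetic data the suite
verifies the machinery end to end: exact count-table reproduction, the
qualitative accuracy-and-bias ordering (full-spectrum baseline worst and
most biased; iPLS better; correction flattens the bias trend), learning-
curve decay, surrogate parameter recovery, and all population-layer numbers
(which depend only on the reference error law, not on spectra). Absolute
RMSE levels and fitted learning-curve coefficients are properties of the
stand-in's information content and transfer to real spectra only
approximately.

## Numerical details

- All randomness flows through `numpy.random.default_rng` seeds; same seed,
  same result, including bootstrap CV, splits, simulations and MCMC
  initialisation.
- Component-count ties use a relative-plus-absolute RMSE slack
  (10⁻⁶ relative, 10⁻⁸·sd(y) absolute) so noiseless fits choose the
  smallest adequate model.
- The P-spline solve adds a 10⁻⁸ ridge to keep the intercept/per-term
  constant overlap identifiable; GCV uses n·RSS/(n − edf)².
- Monte-Carlo defaults: 5 000 replicates for decompositions (50 000 in the
  acceptance script), 4 000–8 000 per grid point for power searches, grid
  step 10 in n.
- Degenerate inputs: constant response → intercept-only PLS; constant raw
  predictions → identity bias corrector with warning; empty samples, grid
  mismatches, overlapping intervals and impossible splits raise typed errors
  (`GridError`, `ConfigurationError`, `SizeError`, ...).

## Known limitations

- The generator does not attempt radiative-transfer realism; its artifacts
  are low-rank smooth curves, and real between-instrument variation is
  likely richer.
- The surrogate's linear mean and linear-in-age noise scale cannot express
  age-dependent bias beyond α + β·age or non-Gaussian error tails.
- Exponential age structure ignores senescence; the population layer is
  explicit about assuming age-independent mortality.
- The bias corrector guarantees monotonicity and approximate conditional
  unbiasedness, not exact per-true-age unbiasedness at the range edges under
  heavy noise.
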