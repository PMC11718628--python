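# Methods

## Scope and data-generating models

`biogaps` studies how gaps in biodiversity monitoring data distort three
common targets — a landscape mean abundance, an environmental-covariate
effect, and a mean population trend — and how far the standard correction
families (subsampling, weighting, post-stratification, imputation)
recover them. Everything runs on synthetic data whose structure is fully
known, so every estimate can be scored against its realized truth.

**Landscape design.** `make_landscape(n_cells, n_levels)` places
`n_cells` cells into `n_levels` equal-count covariate strata; stratum *k*
has raw value (k − 0.5)/K, standardized (population sd, ddof = 0) into
`x_true` with mean 0 / sd 1 exactly. Discretizing the covariate into K
strata is what makes "one cell per covariate value" subsampling and
per-value post-stratification well defined; K = 20 by default and
configurable. The layout carries no spatial autocorrelation — cells are
exchangeable given the covariate. Abundance is log-linear Poisson,
log λ = α + β·x_true (+ optional extra standardized covariates); defaults
α = 1.0, β = 0.8 give counts of order 1–15 across the covariate range and
a landscape mean around 3.7, small enough for single-visit count data and
large enough that covariate-driven sampling produces unmistakable bias.

**Proxy covariate.** The analyst sees `x_proxy`, built by adding Gaussian
noise to `x_true` at mixing weight ρ (latent = ρ·x + √(1−ρ²)·ε) and
re-binning the latent values into K equal-count strata (ties broken by
cell id). The realized Pearson correlation is recorded, never forced; at
ρ = 1 the proxy reproduces the true strata exactly. This construction
keeps the proxy on the same discrete support as the truth, so all four
corrections consume it identically.

**Trend panel.** `simulate_trend_panel` draws site intercepts
a_i ~ Normal(a0, a_sd²) (defaults 2.0, 0.3), places the site covariate u
equally spaced on [0, 1], and sets log λ_it = a_i + (b0 + b1·u_i)(t − 1)
with defaults b0 = +0.02, b1 = −0.10 over 50 sites × 15 years: low-u
sites are stable or mildly increasing, high-u sites decline at up to 8%
per year. Visit-level expansion splits λ_it evenly over visits (uniform
season day, Bernoulli-5/7 weekday flag); no phenology curve or detection
model is applied.

## Missingness mechanisms

`inclusion_probs` maps a covariate to per-unit inclusion probabilities π
under six mechanisms: `constant` (MCAR), `logistic`, `linear` (on the
rank-fraction of the covariate, which avoids clipping pathologies),
`threshold_high`/`threshold_low` (all-or-nothing truncation at the
covariate mean), and `preferential` (logistic in standardized log λ —
MNAR by construction; driven by the expectation rather than the realized
count so the mechanism strength is deterministic). Intercepts are
calibrated by Brent root-finding on [−20, 20] so mean(π) hits the target
sampling fraction to 1e-6; threshold mechanisms solve the retained-side
probability in closed form and report infeasible targets with the bound.
Masks are independent Bernoulli(π) draws; Bernoulli (rather than
fixed-size) sampling keeps units independent, matching the estimators'
assumptions. A mask's `dimension` (spatial / annual / within_year)
controls broadcasting: a spatial mask includes or excludes a site in
every year.

`diagnose_missingness` is a screen, not a decision rule: logistic
regression of inclusion on the supplied covariates (statsmodels GLM),
per-covariate Wald tests plus one likelihood-ratio test against the
intercept-only model, no multiplicity correction, a complete-separation
flag instead of an exception, gap proportions per dimension, and an
unconditional caveat that dependence on unobserved quantities (MNAR) is
untestable from the observed data.

## Estimators

The Poisson IRLS (log link, tolerance 1e-10 on the coefficient step,
≤100 iterations) and the logistic Newton fitter are implemented in
`glm.py`; the sandwich covariance is A⁻¹BA⁻¹ with A the weighted Fisher
information and B the outer product of weighted scores (weights enter the
score, hence squared in B — the survey-weight convention). Both fitters
are cross-checked against statsmodels in the test suite.

- **naive**: intercept-only Poisson GLM; point = sample mean; Wald 95%
  interval on the log scale, back-transformed.
- **subsampled**: `subsample_balanced` keeps min(k, n_h) units per
  observed proxy stratum (k = 1 by default), then the naive estimator.
- **weighted_glm**: Hájek estimator Σ(wy)/Σ(w), w = 1/π̃, as an
  intercept-only weighted Poisson GLM with sandwich variance. Three
  weight sources are supported. The default, `design_proxy`, evaluates
  the known sampling mechanism at the available (proxy) covariate: the
  scheme's design is known, the covariate knowledge is imperfect. This
  choice was made because it is the only weighting reading that
  reproduces both qualitative phenomena at once — weighting clearly best
  on bias at the fixed setting, and weighting degrading as the proxy
  weakens. Estimated propensities (`fit_sampling_model`: logistic
  regression of inclusion on the proxy over all units, π̂ floored at 0.01,
  ridge fallback 1e-4 under separation) barely separate from subsampling
  at ρ = 0.75, because the fitted slope is attenuated toward what the
  proxy explains; true-π design weights are exactly unbiased and
  therefore cannot degrade with ρ. Both remain config switches
  (`weight_mode="estimated"` / `"true"`). Optional weight truncation at a
  quantile guards against extreme weights; off by default.
- **poststrat**: Σ_h N_h ȳ_h / Σ_h N_h renormalized over observed strata;
  population strata with no sample are listed in warnings — this
  renormalization is precisely the failure mode at low sampling
  fractions. Variance is the stratified-sampling formula
  Σ Ñ_h² s_h²/n_h with singleton strata collapsed into the nearest (by
  stratum order) non-singleton stratum for the variance only; interval
  normal-theory on the natural scale.
- **impute**: Bayesian Poisson regression on the proxy, Normal(0, 10²)
  priors, random-walk Metropolis on (a, b) using sufficient statistics
  (per-unique-covariate-value counts), 2 chains × 4,000 iterations with
  2,000 burn-in by default (2,000/1,000 inside Monte-Carlo sweeps). Step
  sizes adapt every 50 burn-in iterations toward 20–45% acceptance and
  are frozen afterwards. Per retained draw the unsurveyed cells'
  posterior-predictive total is one Poisson draw at the summed rate
  (exact, since independent Poissons sum to a Poisson), and the target
  per draw is (observed total + imputed total)/n_cells; point = posterior
  mean, interval = 2.5/97.5 percentiles. Split-chain potential scale
  reduction and effective sample size come from arviz; R̂ > 1.1 raises a
  warning, zero post-burn-in acceptance an error. On census input the
  target is fully observed: the point equals the realized mean and the
  interval has width zero.
- **trend**: Poisson GLM of count on centered continuous year plus site
  indicator terms; the point estimate is the year coefficient
  (log-units/year). Site *fixed* effects are used deliberately: both
  fixed and random intercepts condition on site, which is what the bias
  argument requires, and fixed effects avoid integration machinery
  orthogonal to the phenomenon. Year-as-factor is available
  (slope recovered as the OLS slope through the free year effects).

## Experiments

Each scenario draws per-run seeds from the master seed (counter scheme,
all below 2³¹), so runs are independent and individually replayable, and
identical configs produce byte-identical output CSVs. Within a run every
estimator is scored against the same realized finite-population truth
(the mean of the 400 realized counts; the expectation-based truth is a
config switch), so a census estimator has bias exactly zero. Estimator
failures are counted and excluded from that method's aggregates, never
imputed. Reported metrics: mean bias, Monte-Carlo SE of the bias
(sd/√runs), mean 95%-interval width, empirical coverage of the truth.

Fixed mechanism constants (chosen once, a priori): logistic sampling
slope +2.0 on the standardized covariate (over-surveying of good
habitat, the typical citizen-science gradient; strong enough that the
naive bias is ~60% of the true mean at a 35% sampling fraction); Fig-2
style arms use threshold truncation at the covariate mean and a linear
mechanism with rank-fraction slope −0.7, with quadratic truth generated
by coefficient −0.5 on the standardized squared covariate; the trend
scenario retains 50% of site-years, MNAR via logistic slope +2.0 in
standardized u; the unmodelled-covariate extension adds an independent
standardized covariate with effect +0.5 omitted from the imputation
model.

## Problem sizes and what the tests show

The acceptance suite uses 100 runs per setting for the landscape
comparisons (500 for the MCAR ignorability check, where all five
estimators must sit within 3 Monte-Carlo SEs of zero bias), 500 runs for
the slope-truncation experiment, 200 for the trend experiment, 100
replicates for imputer calibration and 2,000 masks for the diagnostics
null — sizes at which the qualitative orderings are separated by several
Monte-Carlo SEs while the whole suite runs in a few minutes on one CPU.

Because the generator omits overdispersion, detection error, spatial
autocorrelation, phenology and observer heterogeneity, passing tests
demonstrate the *logic* of the missing-data mechanisms and corrections —
not that any correction suffices for real monitoring data, where the
driving covariates are unknown, partially measured, and entangled with
MNAR processes. Selection models, pattern-mixture models, marked
point-process models and instrumental-variable approaches to MNAR are
deliberate extension points, not implemented.

## Numerical conventions

Standardization always uses the population (ddof = 0) standard
deviation. Calibration tolerance on mean(π) is 1e-6; GLM convergence
1e-10 on the max coefficient change; linear predictors are clipped at
±30 inside the fitters to prevent overflow (far outside any scale these
models reach). Proxy binning breaks ties by cell id, making
`attach_proxy` deterministic given its seed. Intervals: Wald on the log
scale for GLM-based landscape estimators, natural-scale normal theory for
post-stratification, percentile credible intervals for the imputer.
Degenerate inputs raise typed errors (`InvalidDesignError`,
`CalibrationError`, `WeightingError`, ...) listed in
`biogaps.exceptions`.
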