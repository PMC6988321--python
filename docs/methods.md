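# Methods

## The model and the precision approximations

`tspower` supports planning of time-series regression studies of counts
on environmental exposures — daily deaths on particulate matter or on
heat, say.  The outcome model is log-linear:

    E(Y_i) = exp(α + β x_i + γ' z_i),

with `Y_i` the event count in period *i* (usually a day), `x_i` the
exposure of interest (log relative-risk coefficient β per exposure unit)
and `z_i` the confounder design — typically a natural spline of date for
season and trend, day-of-week indicators, and possibly other weather or
pollution terms.  Counts may be overdispersed relative to Poisson by a
scale factor φ (quasi-Poisson: Var(Y) = φ·E(Y)).

The core result implemented here is that the sampling standard error of
the fitted β̂ is approximately

    SE*(β̂) = √φ / ( √(ΣY_i) · SD(x|z) ),

where ΣY_i is the **total number of events over the study** and SD(x|z)
is the **usable SD of the exposure**: the standard deviation of the
residuals of a linear regression of x on z.  Two simplifications are
also provided: the crude form with SD(x) in place of SD(x|z) (which
overstates precision whenever the exposure shares variation with the
covariates, e.g. a seasonal exposure against a seasonal spline), and the
pure-Poisson form (φ = 1).  A key property, which the simulation suite
verifies empirically, is that the number of days over which the events
are spread is irrelevant given their total: a 1-year series at 60
deaths/day and a 10-year series at 6 deaths/day have the same planning
precision.

From a standard error the usual planning quantities follow with normal
approximations:

* CI width: 2·z_{α/2}·SE;
* power against an alternative β_H1: Φ(|β_H1|/SE − z_{α/2})
  (two-sided test at level α; the vanishing probability of rejecting in
  the wrong tail is neglected);
* smallest detectable coefficient: (z_{α/2} + z_{1−power})·SE — at
  α = 0.05 and 80% power, 2.8 × SE;
* required events: φ·[(z_{α/2} + z_{1−power}) / (|β_H1|·SD(x|z))]².
  The φ multiplier generalises the pure-Poisson inversion; with the
  default φ = 1 the two coincide.

**Printed-z mode.** All functions take exact normal quantiles
(z_{0.025} = 1.959964…) by default.  A `printed_z` flag rounds each
quantile to two decimals (1.96, 1.28, 0.84), reproducing desk arithmetic
done with rounded z values; the worked example in the README uses it.
The difference is below 0.2% in any output.

## Multi-series (multi-city) studies

A J-series study analysed in two stages (per-series regressions, then
meta-analysis of the β̂_j) admits the same approximation for the
fixed-effect pooled coefficient, with ΣY summed over **all** series:
pooling J homogeneous series is equivalent to one long series with the
combined events.  With between-series heterogeneity of true
coefficients (SD τ, fraction I² of total variance), the random-effects
pooled SE is approximated three ways, in decreasing order of input
requirements:

1. full: √(1/Σ_j (τ² + SE_j²)⁻¹), needing τ and per-series SEs;
2. I²-corrected: SE_FE / √(1 − I²), assuming a common per-series SE;
3. extreme heterogeneity: τ/√J, valid when τ dominates every SE_j.

The pooling machinery itself is an inverse-variance fixed-effect fit and
a DerSimonian–Laird random-effects fit (moment estimator of τ²,
truncated at zero; I² = max(0, (Q − (J−1))/Q)).  DL was chosen as the
closed-form standard for the second stage; likelihood-based estimators
would change nothing structurally.  Series are assumed independent, and
the planning formulas assume SD(x|z) and φ are common across series — a
tractability assumption, not a claim about real networks of cities.

## Usable exposure variation

`exposure.usable_sd` estimates SD(x|z) by OLS of the exposure on the
covariate design the final analysis would use: a natural cubic spline of
date with `df_per_year × span` total degrees of freedom (knots at
equally spaced date quantiles; the spline basis is centred and
orthogonalised so it combines with an explicit intercept at full rank),
day-of-week indicators (Monday reference), and optional extra
covariates entered linearly.  Complete-case analysis; dropped rows are
counted and logged.

Numerical conventions that matter:

* **Residual-SD denominator.** Raw and residual SDs share one
  denominator so that SD(x|z) = SD(x)·√(1 − R²) holds exactly.  The
  default is residual degrees of freedom (n − p), the unbiased-σ
  convention; `denominator="n_minus_1"` is available.  For series of
  epidemiological length the difference is negligible (< 1% at 8 years
  of daily data with 7 df/year).  Note that under n − p, adding a
  useless covariate can *raise* the reported SD slightly (the df
  correction outpaces the RSS drop); strict monotone conditioning holds
  under the n − 1 convention.
* **Percentile convention.** The linear-threshold ("heat") transform
  max(x − q_p, 0) uses linear interpolation between order statistics
  (numpy default, type 7), stated because the threshold value depends
  on it.
* Degenerate inputs raise: rank-deficient designs name the collinear
  columns; R² = 1 (exposure fully explained) is an error, since the
  usable SD is then undefined.

## What the synthetic generator emulates

`simulate` produces series from exactly the model above with a shared
annual seasonal signal s_i = cos(2π·day/365.25 + phase):

* exposure: amplitude·s_i + white noise — so SD(x) and SD(x|z) have
  closed-form expectations, SD(x|z) ≈ noise SD once a seasonal spline
  is fitted;
* outcome linear predictor: log(rate) + β·x_i + coupling·s_i — the
  `coupling` term is the confounding the spline must absorb;
* overdispersion: counts are negative binomial with per-observation
  size μ_i/(φ − 1), giving mean μ_i and variance exactly φ·μ_i (the
  two moments quasi-Poisson specifies), degenerating to Poisson at
  φ = 1;
* multi-city ensembles draw true β_j ~ N(β, τ²) independently.

Defaults are chosen to resemble a mid-sized-city mortality analysis:
4 years of daily data, 20 events/day, β = 0.02 per exposure unit,
exposure amplitude 1.155 with unit noise SD so that R²_x|z ≈ 0.4 (the
seasonality of a heat-type exposure), outcome seasonal amplitude 0.1 on
the log scale, φ = 1.  First-stage fits are statsmodels Poisson GLMs
with Pearson-scaled (quasi-Poisson) standard errors; the Pearson
dispersion φ̂ = Σr²_P/(n − p) is reported alongside.

What the generator deliberately does **not** emulate: residual
autocorrelation, distributed-lag structure, non-linear
exposure–response, missing data, zero inflation, or correlated series.
Passing validation therefore shows the approximators track the model
they were derived for; on real data the dominant error is the planning
inputs themselves (next section).

## Validation design and problem sizes

`validate.validate_single` compares each single-series approximator
with the Pearson-scaled model SE from one long replicate, feeding the
approximators the *realised* event total and exposure SDs profiled with
the same covariate design — this isolates approximation error from
input-estimation error.  The standard grid crosses series length
{1000, 3650} days, baseline rate {5, 20, 50}/day and β ∈ {0, 0.01,
0.02}, plus two scenarios with no exposure seasonality (where crude and
adjusted approximators must coincide); 20 scenarios in all, chosen to
span realistic single-city designs while keeping a full run under a
minute.  Typical results: the covariate-adjusted approximator within a
few percent mean absolute error; the crude approximator biased low by
roughly R²_x|z/2 · 100%.

`validate.validate_multicity` fits a simulated ensemble series-wise,
pools by FE and DL-RE meta-analysis, and scores the pooled-SE
approximators against both fitted references.  Because the fitted DL
τ̂² has sampling noise √(2/J) relative to τ² + SE², a single ensemble's
random-effects comparison is only determined to ~10% at J = 51; the
test suite therefore averages over ten replicate ensembles.

The Monte-Carlo check of day-count irrelevance uses two designs with
the same expected event total (365 days × 20/day vs 1460 days × 5/day)
and 500 simulate-and-fit replicates each; the empirical SD of β̂ agrees
within three Monte-Carlo standard errors.  Replicate counts were sized
so that Monte-Carlo error is well below the effect bands being checked.

All randomness flows from `numpy.random.default_rng([master_seed,
*indices])` with documented index roles (scenario, replicate, series),
so every table is bit-reproducible from its config.

## Known limitations

* The normal-approximation power formula degrades for very small event
  totals (ΣY below a few hundred) where β̂'s distribution is skewed.
* The approximators assume the fitted model matches the generating
  model; confounder misspecification (e.g. too few spline df) biases
  both β̂ and the SE comparison.
* Underdispersion (φ < 1) is accepted with a warning; count data
  exhibiting it usually signal model misfit rather than true
  underdispersion.
* Planning accuracy on real data is limited mostly by how well ΣY,
  SD(x|z) and φ can be guessed in advance — profiling even one year of
  proxy exposure data helps far more than refining the formulas.
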