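# Methods

This note documents the statistical procedures implemented in `burdenqci`,
the choices made where conventions diverge, and what the synthetic-data
tests do and do not establish about real GBD extracts.

## Age-standardized rates and EAPC

Direct standardization: `ASR = Σ_a w_a (count_a / pop_a) × 10⁵` with
standard-population weights `w_a` renormalized over the bins present. A bin
with zero population and zero count contributes nothing; zero population
with positive counts is an error rather than a silently dropped stratum.
The packaged weights are the WHO World Standard Population (2000–2025)
5-year values down to 95+; GBD publishes its ASRs against its own internal
standard, so users replicating GBD numbers must supply that weight file.

EAPC comes from ordinary least squares of `ln(ASR)` on calendar year:
`EAPC = (e^β₁ − 1) × 100`, CI `(e^{β₁ ± z·se} − 1) × 100` with `z = 1.96`.
The normal multiplier is used rather than a t-quantile — with ~32 annual
observations the difference is below reporting precision — and `z` is an
argument for sensitivity analysis. The model is plain homoscedastic OLS on
log rates, not a Poisson or weighted fit: the estimand is the descriptive
log-linear trend of an already-estimated rate series, not a count model.
Rates are carried per 100,000 throughout; rounding to one decimal happens
only in reporting.

## Joinpoint segmented trends

The mean function is continuous piecewise-linear in `ln(rate)`,
parameterized by a truncated-line basis
`ln y = b₀ + b₁ t + Σ_j g_j (t − τ_j)₊`, which enforces continuity at the
joinpoints and makes each candidate placement an OLS fit. Conventions
follow the NCI grid-search defaults where the applied literature is silent:

* candidate joinpoints sit on observed years, endpoints excluded, with at
  least 2 observations between joinpoints;
* for each k the placement minimizing RSS is found by exhaustive search;
* the number of joinpoints is decided by sequential Monte Carlo permutation
  tests (k vs k+1): residuals of the best null fit are permuted, both
  models are refitted on each permuted series, and the RSS-ratio statistic
  is compared with its permutation distribution,
  `p = (1 + #{T* ≥ T}) / (n_perm + 1)`;
* BIC (`n·ln(RSS/n) + p·ln n` with `p = 2 + 2k`, counting slopes and
  breakpoint positions) is computed for every candidate k and reported; when
  BIC and the permutation decision disagree, the permutation decision wins,
  since the test is the explicit significance gate;
* the default `n_perm = 999` is a desk-scale choice (the NCI tool defaults
  to 4499); it is configurable, and fits are deterministic given the seed.

Per-segment slope covariances come from the OLS coefficient covariance via
the linear map from hinge coefficients to segment slopes. APC CIs use
`z = 1.96`; AAPC over a span is `(exp(Σ w_j b_j) − 1) × 100` with `w_j` the
fraction of the span in segment j, and its CI and p-value come from the
delta method on the slope covariance. The permutation-test calibration suite
(500 null simulations at `n_perm = 199`) checks the empirical type-I error
against a 3-sigma binomial band around α.

## Change decomposition

An all-ages count factorizes as `C(t) = N(t) · Σ_a s_a(t) · c_a(t)`
(total population × age shares × age-specific rates). Each per-bin term is
a three-way product, so the Das Gupta symmetric averaged-substitution
formula applies bin by bin:

    effect(α) = (α₂ − α₁) · [(β₁γ₁ + β₂γ₂)/3 + (β₁γ₂ + β₂γ₁)/6]

and cyclically for the other two factors. This is algebraically identical
to averaging sequential substitution over all 6 factor orderings, which the
tests verify against an independent brute-force implementation; additivity
`ΔC = ΔC_epi + ΔC_age + ΔC_pop` is exact, with no interaction residual term. Results are reported in counts; a per-100,000-of-baseline scaling is
available via `DecompositionResult.scaled`. Both-sex decompositions are run
on both-sex inputs rather than summing sex-specific components — the method
is not linear in its factors, and the difference is real, not an error.

## Quality of Care Index

Four ratio indices per stratum proxy care quality: prevalence/incidence
(higher = better disease control and survival), deaths/incidence (MIR,
higher = worse), DALY/prevalence (burden per prevalent case, higher =
worse), YLL/YLD (fatal vs non-fatal mix, higher = worse). The DALY index
divides by prevalence by default — that is what "burden per prevalent case"
means — with `daly_denominator="incidence"` available because both
conventions circulate in the applied QCI literature.

Construction: z-standardize each index over the observation pool;
eigendecompose the 4×4 correlation matrix (PCA on standardized indices is
exactly correlation-matrix PCA); take the top two eigenvectors; fix each
component's sign so it correlates non-positively with MIR (eigenvectors are
sign-ambiguous, and this makes "higher score = better care" hold by
construction); combine with weights `λᵢ/(λ₁+λ₂)`; min-max scale to 0–100
over a scaling pool.

Pooling: by default all observations passed in one run form both the PCA
pool and the min-max pool, because cross-year comparability (e.g. 1990 vs
2021) requires a shared scale; a per-year policy is available. Columns that
are constant over the pool are dropped before PCA (constancy is judged
relative to column magnitude — ratios constant by construction carry
~1e-16 float noise whose z-scores would be amplified garbage). A pool of
identical observations maps every stratum to 100; fewer than 3 observations
or fewer than 2 varying indices is a degenerate-pool error. Ratios are not
log-transformed before z-scoring by default; a flag exists for heavy-tailed
pools.

## ARIMA projection

Box–Jenkins ARIMA(p, d, q) per series: d is the smallest order (≤ 2) at
which the augmented Dickey–Fuller test rejects at 0.05; (p, q) come from a
maximum-likelihood grid (defaults p, q ≤ 3) ranked by AIC or BIC — a
reproducible replacement for visual ACF/PACF identification, with ACF/PACF
values attached for inspection. A constant term is included for d = 0 and a
drift term for d = 1; residual whiteness is summarized by the Ljung–Box
p-value at lag `min(10, n/5)`. Prediction intervals are model-based
Gaussian intervals; no bootstrap option. In-sample information criteria and
diagnostics are reported — no train/validation split is imposed on
three decades of annual data. Series shorter than 30 points trigger a
warning: projections from such series are extrapolative baselines, not
scenario forecasts. An all-constant series returns a flagged degenerate fit
(constant forecast, zero-width interval).

## Synthetic data generator

The generator emulates a GBD extract's stratification: 5-year age bins
(<5 … 95+, top-bin midpoint 97.5 years), both sexes, annual series over a
configurable span, number and rate metrics, sex=both / all-ages /
age-standardized aggregate rows. Ground truth per measure:
`rate(a, sex, t) = base_rate · exp(−(mid(a) − age_mode)²/(2·age_sd²)) ·
sex_ratio^{[female]} · (1 + APC/100)^t`, counts are `pop · rate / 10⁵`
times mean-one lognormal noise with coefficient of variation `noise_cv`
(multiplicative noise keeps counts positive and the log-linear EAPC model
well-specified). YLLs are a fixed share of DALYs and YLDs the complement,
so `DALY = YLL + YLD` holds exactly. The population panel is noise-free:
totals grow geometrically and the age distribution is a discretized
Gaussian whose mode drifts by `aging_shift` per year (an error if the drift
leaves the bin range). Bimodal age patterns are composed by summing two
scenarios. Default magnitudes (base rates of 1.5 / 30 / 0.25 / 14 per 10⁵
for incidence / prevalence / deaths / DALYs, trends of ±0.3–0.9%/yr,
female:male ratio 2, noise CV 0.05) are of the order seen in multiple
sclerosis burden tables, making the scenarios realistic for the trend,
decomposition and QCI machinery exercised on them.

What passing recovery tests show: the estimators correctly invert the
generator's data model. What they do not show: robustness to features of
real GBD estimates the generator omits — serially correlated estimation
error from the GBD modeling pipeline, draw-based uncertainty intervals,
cohort effects, non-Gaussian age patterns, and abrupt reporting shocks.
Upper/lower columns are normal-approximation bands around the value, not
draw quantiles, and no uncertainty propagation through the analyses is
attempted.

## Numerical and interface choices

* Tables are pandas DataFrames in the GBD results-tool column order; labels
  are normalized to canonical short strings on read and written back with
  6-significant-digit floats (so consecutive writes are bit-stable and
  diffable; identity checks on re-read use a tolerance matching that
  precision).
* All randomness (generator noise, permutation tests) flows through
  `numpy.random.default_rng` seeded from explicit arguments; every fit is
  deterministic given its inputs and seed.
* The trend column of published burden tables is sometimes labelled EAPC
  and sometimes AAPC; the package computes both (EAPC from the single
  log-linear fit, AAPC from the joinpoint model) and leaves the choice of
  summary to the analyst.
* Monte Carlo suite sizes in the tests and acceptance script (1000 EAPC
  replicates, 500 joinpoint null simulations at `n_perm = 199`, 200 AR(1)
  replicates) are the package's desk-scale study conditions: large enough
  for 3-sigma binomial bands around the nominal rates, small enough to run
  on one CPU in minutes.

## Known limitations

* Not bit-compatible with the NCI Joinpoint tool (different permutation
  count defaults, tie-breaking and variance conventions); no
  autocorrelated-error joinpoint variant.
* Decomposition and QCI consume already-estimated tables; nothing here
  re-estimates epidemiology from primary data.
* The QCI depends on its pool: scores are comparable only within one
  construction run, and the choice of pooling policy is part of the
  analysis design.
* ARIMA on ~30 annual points identifies only low orders reliably; the grid
  is capped accordingly and projections should be read as baselines.
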