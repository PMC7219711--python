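# Methods

## The model

The package estimates a two-stage random-coefficients model for a
country-year panel of adult obesity prevalence (%, by sex stratum) and GDP
per capita (GDPPC, constant units).  The first stage is a per-country
log-log regression

    ln(prev_ct) = α_c + β_c ln(gdppc_ct) + ε_ct,   ε_ct ~ N(0, σ_c²),

so β_c is the income elasticity of obesity prevalence.  The second stage
regresses the country coefficients on standardized cross-sectional
moderators x_c (an intercept plus covariates tagged with one of five
macro-environmental dimensions):

    (α_c, β_c)' = (x_c'θ_α, x_c'θ_β)' + π_c,   π_c ~ MVN(0, Σ).

Assumptions worth stating: the elasticity is constant within a country over
the panel window (the sensitivity scenarios relax this by re-estimating on
recent windows); the error variance is homoskedastic within country — a
per-country-year variance would be unidentifiable from single observations;
moderators are time-invariant (they are measured cross-sectionally);
strata (male, female, overall) are modelled independently.

## Estimation

Both stages are estimated jointly by a Gibbs sampler whose four blocks are
all conjugate:

1. **Country coefficients** (α_c, β_c): MVN full conditional combining the
   country's least-squares information X_c'X_c/σ_c², X_c'y_c/σ_c² with
   prior mean Δ'x_c and precision Σ⁻¹.  Implemented with closed-form 2×2
   inverses and Cholesky factors, vectorized over countries.
2. **Error variances** σ_c²: scale-inv-χ²(ν₀+T_c, (ν₀s₀² + SSR_c)/(ν₀+T_c)).
3. **Σ**: inverse-Wishart IW(ν+n, V+S), collapsed over Δ under the
   conjugate matrix-normal prior (S is the second-stage residual
   cross-product including the prior-shrinkage term).  Sampled by the
   Bartlett decomposition.
4. **Δ** (columns θ_α, θ_β): matrix-normal MN(Δ̃, (Z'Z+A)⁻¹, Σ), with the
   Cholesky factors of Z'Z+A and its inverse computed once per run.

Priors are weakly informative conjugate defaults, all configurable:
Δ | Σ ~ MN(0, A⁻¹I, Σ) with A = 0.01; Σ ~ IW(ν, νI) with ν = dim+3 = 5;
σ_c² ~ scale-inv-χ²(ν₀ = 3, s₀² = 1) on the log-prevalence scale.  Each
block's sampler is tested against its closed-form conditional moments, and
parameter recovery on replicated synthetic panels checks that 95% credible
intervals for θ_β cover the generating values at near-nominal rates.

**Chain settings.**  Default 50,000 iterations; the first 30,000 raw
iterations are discarded as burn-in and every 10th of the remainder is
retained (2,000 draws).  Alternative readings of burn-in/thinning order
give the same magnitude and are expressible through `MCMCConfig`.  All
randomness flows from one seed through per-block `SeedSequence` children,
so instrumenting one block never perturbs another's draws; identical
configurations reproduce draws bit-exactly.

**Summaries.**  Credible intervals are equal-tailed 2.5/97.5 percentiles
(not HPD), matching the (lower, upper) presentation convention.  The
headline "mean income elasticity" is the posterior of the unweighted
cross-country average of β_c draws; the second-stage intercept θ_β,0 is
reported alongside and generally differs (moderators are standardized, but
the average is over the realized countries, not the model intercept).

**Convergence.**  Geweke Z compares the first 10% of a chain with the last
50%, standardized by spectral-density-at-zero estimates from a
Bartlett-windowed autocovariance sum with window ⌈4(n_seg/100)^0.25⌉.
|Z| < 1.96 declares convergence; i.i.d. chains of length 2,000 pass at
93–97%.  Short demo chains (a few hundred retained draws) can
false-positive — the first segment is then only a few dozen points — so
the pipeline treats an exceedance as a soft warning, not a failure.

## Functional-form contest

Linear, quadratic and log-log first stages are fit per country by OLS and
compared by the mean absolute percentage error of fitted prevalence on the
original % scale, which requires exp back-transforming the log-log fits —
comparing a log-scale model with %-scale models by one MAPE number is only
coherent on a common scale.  No smearing correction is applied to the
back-transform (a small known bias, listed under limitations).  MAPE is
in-sample: this is a fit comparison, not cross-validation.  Per-country
OLS (not the full sampler) is used inside the contest, since only relative
fit matters and shrinkage affects all forms similarly; the hierarchical
model is then estimated for the log-log form.  GDPPC is rescaled to
thousands inside the quadratic so the squared column stays well
conditioned.  Note that in-sample the quadratic, with one extra parameter
per country, can edge out log-log on log-log-generated data; the linear
form loses essentially always, which is the contest's decisive margin.

## Moderator selection

Selection runs in a fast two-step mode: the response is the vector of
per-country OLS elasticities, and candidate fits are OLS regressions
scored by AIC and BIC (BIC wins disagreements — parsimony).  Phase 1 adds
one variable per macro-environmental dimension (five rounds); a candidate
must have |t| above the 5% critical value, else the best-criterion
candidate is taken with a warning.  Phase 2 keeps adding any remaining
admissible candidate while BIC improves.  Pairs of moderators with
|Pearson r| > 0.7 (configurable) are mutually exclusive throughout.  The
criterion is computed on the elasticity (β) equation, the scientific
target; the α equation is refit with the same selected set inside the
final Gibbs run.  The procedure is deterministic given its inputs.  The
full sampler is deliberately not run inside the selection loop.

## Forecasting

For each posterior draw b of a country's elasticity, prevalence compounds
yearly along the projected income-growth path:

    prev_{y+1} = prev_y · (1 + s_y β_b g_y / 100),

where g_y is annual GDPPC growth in % (actual growth over bridge years
between the panel end and the projection horizon, projected growth over
the horizon) and s_y is the scenario's elasticity factor: a linear ramp
reaching the full decline d in the final horizon year (bridge years always
s=1; a step mode is available).  Elasticity draws are thinned to exactly
1,000 joint posterior draws (resampled with replacement if fewer are
retained), keeping the draw index shared across countries so each
trajectory set is a coherent joint draw.  Aggregation across countries is
an unweighted mean per draw; bands are 2.5/97.5 percentiles across draws.
The reported "average annual growth" is the CAGR of the aggregate mean
trajectory over the horizon (the mean of per-year growth rates is reported
alongside).  Because draws are aggregated before summarizing, the mean
trajectory is not exactly the trajectory of the mean elasticity (Jensen
gap); tests assert the mean lies within the band instead.  Prevalence is
clamped to (0, 100] with an event counter rather than silently truncated;
on small synthetic configs no clamping occurs, while at the full default
scale a fraction of order 0.1% of country-draw-years clamps, driven by the
few highest-prevalence countries drawing large elasticities.

The five standard scenarios: elasticities from the full window, the most
recent 15 years, the most recent 10 years, and the recent-10-year
estimates with total declines of 10% and 20% ramped over the horizon.

## The synthetic-data generator

The generator emulates the structure of a WHO/World-Bank-style panel: 147
countries × 40 years (labelled 1975–2014), log-log truth with country
coefficients drawn from the second-stage law, multiplicative observation
noise (σ_y = 0.05 on the log scale, giving the tight national time-series
fits such data show), GDPPC trajectories that are geometric with Gaussian
log-shocks (country mean growth ~ N(0.02, 0.01²), yearly shocks
N(0, 0.02²)), baseline log-income ~ N(8, 1.5²), ten moderators (two per
dimension, two binary), and an IMF-style projection table (2015–2018
bridge, 2019–2024 horizon).  Default truth: mean elasticity 1.2 on the
intercept, −0.15 on the income-linked moderator, ±0.1 on one further
moderator per dimension, Σ = [[0.68, −0.08], [−0.08, 0.01]].

Two structural choices deserve explanation:

* **Income-linked moderator.**  The first continuous moderator indexes
  baseline log-income (ln gdppc₀ = 8 + 1.5 z₁), and the default θ_α
  carries an offsetting loading on it.  Real panels show exactly this
  pattern: within-country elasticities near 1.2 coexist with a much
  flatter cross-sectional gradient, which is only possible when country
  intercepts are negatively correlated with income.  Without the link, a
  1.2-elasticity log-log law over incomes spanning e⁵–e¹¹ would drive a
  large share of countries past 100% prevalence.  The link also makes the
  negative elasticity loading on that moderator the synthetic analogue of
  the urbanization-style attenuation seen in real data.  It can be
  switched off (`income_linked_moderator=False`) for configurations with
  narrower income dispersion.
* **Reject-and-redraw, never truncate.**  A country whose simulated
  prevalence exits (0, 100) has its coefficient deviation and noise
  redrawn (up to 1,000 attempts, else a config-infeasibility error);
  truncation would distort the log-log structure the estimator assumes.
  Under the default configuration the redraw rate averages ≈ 0.3% of
  country-stratum draws, so the effective generating distribution is
  essentially the stated one.

What the generator does **not** emulate: real-world country marginals
(actual prevalence distributions, named countries, real GDP series),
measurement-error autocorrelation in the WHO estimates, time-varying
moderators, or sex-specific elasticity gaps (strata are independent draws
from the same law).  Passing recovery tests therefore demonstrate that the
estimator recovers the model's own data-generating process at realistic
scale and noise — not that the model is correctly specified for any real
panel.

## Numerical choices and degenerate inputs

2×2 inverses and Cholesky factors use closed forms; Σ = 0 in the generator
degenerates cleanly to zero deviations (eigenvalue-clipped matrix root);
zero-variance non-dummy covariates raise a named error rather than
producing NaNs; SSR is clipped at zero against rounding; constant chains
are a degenerate-chain error in the diagnostic; MAPE requires strictly
positive actuals (guaranteed by the panel invariant prevalence ∈ (0,100));
form-contest ties within 1e-9 are flagged and resolved to the first-listed
form.  CSV I/O writes 17 significant digits and reads with round-trip
float parsing, so write/read round trips are bit-exact.  CAGR uses
interval counts (1975→2014 is 39 intervals).

## Problem sizes used by the test suite and acceptance script

Parameter-recovery runs use 50 replicates of 147×40 single-stratum panels
at 5,000 iterations (burn-in 3,000, thin 5); the acceptance script uses 20
such replicates for coverage, 50 panels for the form contest, 1,000 chains
for Geweke calibration, and 1,000 elasticity draws with a 2,000-iteration
chain per estimation window for the scenario table.  These sizes give
Monte-Carlo error comfortably inside the tolerances being checked.

## Known limitations

* No smearing correction on the log-log back-transform (MAPE comparison
  carries a small transformation bias common to all seeds).
* Homoskedastic-within-country errors; no missing-data handling.
* Selection criteria are computed on the β-equation only.
* Forecasts hold the moderator structure fixed and treat projected growth
  as exogenous and certain; prediction intervals reflect elasticity
  uncertainty only.
* No alternative samplers (Metropolis/HMC) and no marginal-likelihood
  model comparison.
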