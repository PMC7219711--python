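# obesity-elasticity

Hierarchical Bayesian estimation of the relationship between national income
and adult obesity prevalence.

At a country level, obesity prevalence rises with affluence, but the pattern
and strength of that relationship vary widely across countries, and the
macro-environment (globalization, demographics, economic structure, labor
markets, health policy) can amplify or dampen it.  This package estimates
**country-specific income elasticities of obesity prevalence** — the % change
in prevalence per 1% change in GDP per capita — from a country-year panel,
identifies cross-sectional moderators of those elasticities, and forecasts
prevalence from projected income growth.  It is aimed at epidemiologists and
health economists working with WHO-style prevalence panels and World-Bank
style income series; because such data cannot be redistributed here, the
package ships a synthetic-panel generator with recorded ground truth that
reproduces the statistical structure the estimator assumes.

## Model

First stage, per country *c*, year *t* (log-log form, chosen by a MAPE
contest against linear and quadratic alternatives):

```
ln(Obesity_prev_ct) = α_c + β_c ln(GDPPC_ct) + ε_ct,   ε_ct ~ N(0, σ_c²)
```

Second stage, cross-sectional, with standardized moderators x_c:

```
[α_c, β_c]' = [x_c'θ_α, x_c'θ_β]' + π_c,   π_c ~ MVN(0, Σ)
```

Both stages are estimated jointly by a Gibbs sampler with conjugate blocks
(per-country MVN coefficients; per-country scale-inv-χ² error variances;
matrix-normal second-stage coefficients; inverse-Wishart Σ), default 50,000
iterations with 30,000 burn-in and thinning by 10.  Moderators — at least
one from each of five macro-environmental dimensions — are chosen by
forward selection under AIC/BIC with a pairwise-correlation screen.
Convergence is checked with Geweke Z-scores.  Forecasts compound prevalence
yearly, `prev ← prev·(1 + s·β·g/100)`, over 1000 posterior elasticity draws
per country, with sensitivity scenarios that re-estimate β from recent data
windows and ramp elasticities down by 10–20%.

## Worked example

`examples/03_hierarchical_fit.py` generates a 147-country × 40-year panel
with true mean elasticity 1.2 and five active moderators, fits the
hierarchical model with a shortened chain, and prints:

```
mean income elasticity: 1.204 (95% CI 1.176, 1.233); truth 1.200

second-stage elasticity-equation coefficients:
 variable  estimate  lower  upper  significant
intercept     1.234  1.149  1.311         True
      m01    -0.135 -0.173 -0.091         True
      m02    -0.106 -0.145 -0.067         True
      m03    -0.089 -0.136 -0.045         True
      m04     0.100  0.057  0.144         True
      m05    -0.120 -0.167 -0.079         True
      m06    -0.009 -0.052  0.031        False
      ...
true theta_beta: [ 1.2  -0.15 -0.1  -0.1   0.1  -0.1   0.    0. ...]
```

The cross-country mean elasticity recovers the generating value, the five
active moderators (m01–m05) are flagged significant with estimates near
their true effects, and the noise moderators are not.  The other examples
cover the panel descriptives (group means, CAGR), the functional-form
contest, moderator selection, scenario forecasting, and the one-call
pipeline (`run_full_analysis`) that writes `mape_table.csv`,
`selection_trace.csv`, `summary.csv`, `elasticities.csv`, `forecast.csv`
and a run report.

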