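# Methods

`sanburden` estimates deaths attributable to unsafe sanitation in rural
populations (DAUSRs) from country-year panels, projects the burden a decade
ahead, and attributes changes in the burden to demographic, sanitation and
mortality drivers. This note documents the models, their assumptions, the
numerical choices, and what the synthetic test worlds do and do not show.

## Attribution model

For country *c*, year *t*, age band *a* and cause *d* (diarrheal disease by
default), attributable deaths are

    DAUSR_t = sum_{a,d} POP_t * AgeP_{a,t} * Rate_{a,d,t} / 100000 * PAF_{a,d,t}

where `POP_t` is the rural population (total population x rural share),
`AgeP_{a,t}` the age-share vector and `Rate_{a,d,t}` the cause-specific death
rate per 100,000. The population attributable fraction for one exposure
category with prevalence *p* and relative risk *RR* uses the discrete
comparative-risk-assessment form

    RRbar = p (RR - 1) + 1 ,   PAF = (RRbar - 1) / RRbar ,

and independent factors combine multiplicatively,
`PAF = 1 - prod_A (1 - PAF_A)`. Exposure lives on a three-rung sanitation
ladder — sewer/septic connection (referent), other improved facilities,
unimproved facilities — normalized from survey counts by

    sewer      = sewered / nonmissing
    improved   = (improved among non-sewered / non-sewered) * (1 - sewer)
    unimproved = 1 - sewer - improved .

When every respondent is sewered, `improved` is taken as its 0/0 limit, 0.

**Assumptions made explicit.** (1) The rural subpopulation shares the age
structure of the total population; the pipeline logs this assumption on
every run. (2) Relative risks are constant over time and age unless
age-specific records are supplied. (3) Protective relative risks (RR < 1)
are rejected by default; a `clamp_protective` switch clamps their PAF at 0
instead. (4) Whether "unsafe" means the unimproved rung alone or unimproved
plus improved is configuration (`unsafe_fraction` definition), not a claim:
the default attribution applies one PAF factor per non-referent rung with
its own RR, which subsumes both readings.

## Age standardization

Age-standardized rates are directly standardized:
`ASR = sum_a w_a * (deaths_a / rural population_a) * 100000`. Default
weights are the WHO World Standard Population aggregated onto the configured
age schema and renormalized; any weight vector on the schema is accepted.
Group-level ASRs are recomputed from pooled age-specific deaths and
populations, never averaged over member ASRs.

The default age schema is `{<5, 5-14, 15-49, 50-64, 65+}` — the coarsest
partition that isolates the two high-risk groups for diarrheal mortality.
The schema is configurable and carried in every config object.

## Bayesian age-period-cohort mortality model

Per country, observed log rates decompose as
`log mu_ijk = alpha + A_i + P_j + C_k + eps`, with Gaussian `eps` (inputs
are rates, not counts, so a Gaussian on the log rate is the faithful
likelihood; a count likelihood is a documented extension point). The age,
period and cohort effect vectors carry second-order random-walk (RW2)
smoothing priors with Gamma(1, 0.01) hyperpriors on their precisions;
`alpha ~ N(0, 100^2)`; the residual variance has an inverse-gamma(1, 1e-4)
prior so that noise-free surfaces are handled without degeneracy.

*Cohorts.* Age bands have unequal widths, so cohorts are indexed by 5-year
bins of `year - band midpoint` (open-ended bands use `lower + 10` as their
midpoint).

*Identifiability.* The APC design is rank-deficient by 4: one level per
effect vector plus the exact linear dependence cohort = period - age. The
model is identified by sum-to-zero constraints on all three vectors plus a
zero-slope constraint on the cohort effects, attributing the surface's
entire temporal drift to the period effect (the classical drift-to-period
convention, which is also what projection extrapolates). Constraints are
enforced exactly on every posterior draw and recorded in the posterior's
constraint record.

*Sampling.* All full conditionals are conjugate (the joint effect block is
Gaussian given the variances; variances are gamma/inverse-gamma given the
effects), so the posterior is explored by a blocked Gibbs sampler: one
joint Gaussian draw of (alpha, A, P, C) per iteration via dense Cholesky
factorization of the ~50-dimensional precision matrix, with the linear
constraints imposed by conditioning-by-kriging, then conjugate variance
updates. Defaults: 2 chains, 1000 retained draws after 500 warm-up
iterations per chain, seeded per chain from a single integer seed.
Split-chain R-hat (via arviz) must be <= 1.05 on all reported parameters,
otherwise the fit is flagged and projection is refused unless forced (the
pipeline forces and logs).

*Projection.* Period (and newly needed cohort) effects are extended under
their RW2 dynamics per posterior draw — the RW2 mean forecast continues the
local linear trend with innovation variance drawn from the posterior — and
per-draw rate trajectories are exponentiated and summarized. The point
projection is the posterior **median**: on a log-scale model the mean of the
exponential inflates with forecast variance at long horizons, which would
manufacture a spurious late-horizon upturn. Intervals are the 2.5/97.5
percentiles and widen with horizon by construction.

*Degenerate inputs.* Zero rates are replaced by half the smallest positive
rate in the surface before logging, with a logged warning. Fits require at
least 3 age bands and 5 periods.

## Compositional ARIMA forecasting of sanitation shares

Sanitation share triples are forecast per country under a simplex
constraint. The default mode maps each triple to two additive-log-ratio
coordinates with sewer as reference, forecasts each coordinate with a
univariate ARIMA(p, d, q), and back-transforms, so point forecasts sum to
1 exactly. Order selection minimizes AICc over a grid (default p, q <= 2,
d seeded by an augmented Dickey-Fuller test and refined over {d0, d0+1}),
with ties broken toward the smallest p + d + q and then the smallest p —
parsimony matters for the ~20-point annual series the pipeline sees.
Estimation, forecasting and Gaussian prediction intervals are delegated to
statsmodels with stationarity and invertibility enforced; constant series
short-circuit to an exact flat forecast with zero-width intervals.

Per-component 95% bounds are obtained by back-transforming one coordinate's
interval endpoints with the other coordinate at its point forecast (and
both endpoints jointly for the reference component). These are
componentwise intervals — they ignore cross-coordinate dependence — and are
clipped to bracket the point forecast. An alternative `independent` mode
forecasts the three shares separately, clips to [0, 1] and renormalizes;
its output is flagged. Zero shares are floored at 1e-6 (logged) before the
log-ratio transform.

## Uncertainty propagation

The 95% bounds on attributable deaths are computed by endpoint
substitution: the lower bound evaluates the attribution formulas at the
lower limits of the exposed shares, the mortality rates and (by default)
the relative risks; the upper bound at the upper limits. Attributable
deaths are monotone increasing in each of those inputs, so the bounds
bracket the point estimate by construction. RR limits can be switched off
(`include_rr_bounds=False`) for a strictly narrower scheme. Observed years
carry degenerate share bounds (surveys enter as points); projected years
carry the forecast intervals. Population is treated as fixed — projected
population variants are not propagated. A Monte Carlo mode that samples
shares, rates and RRs within their intervals is provided purely as a
cross-check of the endpoint scheme.

## Driver decomposition

The change in attributable deaths between two snapshots is attributed to
five factors: rural population size, the 65+ age share, the under-5 age
share, the sanitation share triple, and the age-specific mortality rates
(relative risks held fixed). A factor's contribution is its marginal
effect averaged over all orderings of factor introduction — the Shapley
value of the coalition function "deaths with factor subset S at its later
value" — so contributions sum to the total change exactly and an unchanged
factor contributes exactly zero. A four-factor grouping (single
age-structure factor) is available by configuration.

Because the 65+ and under-5 shares are separate factors, swapping one holds
the other fixed and rescales only the interior age bands proportionally to
keep the simplex. This is the minimal-assumption definition of a partial
age-structure counterfactual and keeps the factor components disjoint.

The default implementation memoizes the 2^5 = 32 subset evaluations and
applies Shapley weights; explicit enumeration of all 120 orderings is kept
as a test oracle (`decompose_naive`). Exhaustive computation is refused
above 8 factors. Aggregated ("GLOBAL") contributions are sums of
per-country contributions, so aggregate efficiency is inherited.

## Synthetic worlds

The generator produces country-year-age panels with the structure the
analysis assumes, for fully self-contained testing:

* **Population**: log-linear growth with country rates drawn from
  [0, 2]% per year; the 65+ share drifts up (default 0.15 percentage
  points/year) and the under-5 share down symmetrically, renormalized on the
  simplex with a 1% floor; rural share constant per country in [0.3, 0.7].
* **Sanitation**: the unimproved share declines along a country-specific
  logistic (midpoint 2005-2020, slope 0.08-0.20/yr, start level 0.4-0.8)
  with optional logit-scale noise; the remainder splits between sewer and
  improved with the sewer fraction rising linearly.
* **Mortality**: log-rate APC surface with a U-shaped age profile (elevated
  under 5 and over 65), linear period decline (default -0.04/yr), small
  random-walk cohort effects (sd 0.05/bin) and i.i.d. log-scale noise
  (sd 0.05); baseline rates 20-80 per 100,000; 95% bounds are
  `rate * exp(+-1.96 * 0.10)`.
* **Relative risks**: fixed configuration, default 2.5 (1.8-3.2) for
  unimproved and 1.3 (1.1-1.6) for improved exposure. These are settings,
  not epidemiological claims.

Generators are pure functions of (config, seed); per-country substreams are
derived from `SeedSequence(seed, spawn_key=(stream, country))`, so adding a
country never changes another country's panel. Each generator stores its
ground truth (growth rates, APC effects in the identified parameterization,
logistic parameters) for recovery tests that never consult it during
fitting.

What the synthetic worlds do **not** emulate: survey measurement error and
reweighting, COVID-era mortality shocks, migration between rural and urban
strata, correlation between sanitation progress and mortality decline
beyond what the pipeline models, and real-world magnitudes. Passing tests
demonstrate the pipeline's correctness and its qualitative behavior under
the assumed data regime, not agreement with any real-world total.

## Problem sizes and defaults used in checks

The packaged checks run the pipeline at 10 countries, a 2000-2020 annual
history, and projection to 2030, with the APC sampler at 2 chains x 400
draws (250-1000 in unit tests) — enough for stable posterior summaries of
a ~50-parameter conjugate model while keeping a full run around a minute.
Parameter-recovery checks use 20 independent surfaces at 2 chains x 1000
draws and 100 seeded AR(1) replicates. `scripts/acceptance.py` re-runs the
full pipeline at these sizes from a single seed and reports the global
burden trajectory, age-standardized rates, the projected unimproved share,
and the five factor contributions.

## Known limitations

* The Gaussian-on-log-rate likelihood ignores the varying populations
  behind the rates; a Poisson/negative-binomial option would weight small
  countries' noisy rates more faithfully.
* One APC model per country: no hierarchical pooling, so short or noisy
  surfaces get wide intervals rather than borrowed strength.
* RW2 period extrapolation means long-horizon credible intervals grow
  roughly like horizon^(3/2) and can be very wide; that is honest about
  what a trend model knows, but a practitioner may want drift-damping.
* Compositional forecast bounds are componentwise, not joint.
* Endpoint-substitution death bounds treat input intervals as perfectly
  dependent (all-low vs all-high), which is conservative relative to the
  Monte Carlo cross-check.
* Countries with any missing cell are excluded outright (no imputation),
  matching the source-data policy the pipeline is built around.
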