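# Methods

`rasprt` replays a statewide hospital-mortality surveillance evaluation end
to end: a synthetic clinical registry, rolling monthly logistic risk models,
a per-hospital risk-adjusted sequential probability ratio test (RA-SPRT)
with annual resets, a Bayesian hierarchical profiling "gold standard", and a
hospital-year confusion evaluation of the two. This note records the models,
the defaults and the design choices that were genuinely open.

## The sequential test

For hospital *j*, cases are analysed in procedure-date order. Case *i* with
model-predicted death probability `p_i` and observed outcome `O_i ∈ {0,1}`
contributes the increment `O_i − s_i` to a cumulative statistic `T`, where

    s_i = ln((1 − p_i) + OR·p_i) / ln(OR)

and `OR` is the alerting odds ratio — the multiplicative odds elevation the
test is powered against. `T` starts at 0 and is compared with the Wald
boundaries on the same ln(OR)-scaled axis:

    h1 = ln((1 − β)/α) / ln(OR)        (accept the elevated-odds hypothesis)
    h0 = ln(β/(1 − α)) / ln(OR)        (accept the null)

`T·ln(OR)` is exactly the textbook Wald log-likelihood-ratio sum for testing
`p_i` against `p1_i = OR·p_i/(1 − p_i + OR·p_i)`; the test suite asserts
this identity against an independently coded oracle. Defaults are α = 0.05,
β = 0.10, OR = 2.0, giving h1 = ln 18/ln 2 ≈ 4.1699 and
h0 = ln(0.10/0.95)/ln 2 ≈ −3.2479.

Design choices that the source formulation leaves open:

* **Lower boundary sign.** The lower limit is taken as ln(β/(1−α))/ln(OR),
  the standard Wald accept-null boundary (negative, as an accept-null limit
  must be); this matches the Spiegelhalter/Rogers risk-adjusted CUSUM/SPRT
  lineage.
* **Annual reset.** Surveillance is truncated at each reporting-period
  boundary and `T` restarts at 0 (`reset_policy="annual"`), so verdicts align
  with annual public reports; a continuous mode (`"none"`) is provided.
  Truncation discards accumulated evidence, so the per-period false-alert
  rate is below the nominal α of the untruncated test — the operating-
  characteristics simulation quantifies this.
* **Post-crossing behaviour.** Within a period, after either boundary is
  attained the statistic resets to 0 and monitoring continues
  (`post_crossing_policy="reset_to_zero"`); the period's alert flag is "h1
  crossed at least once". An `"absorb"` mode stops at the first crossing.
* **Ties.** A boundary attained counts as crossed, with tie tolerance 1e-12.

## Rolling risk adjustment

For each analysis month a standard logistic regression (maximum likelihood,
IRLS via statsmodels GLM) is fitted on the pooled statewide cases of the
prior up-to-11 months and applied to every case of the current month. The
first study month is training-only and never scored; early months train on
one to ten months. Months whose window contains no deaths or no survivors
are skipped and their cases excluded from surveillance, with a log entry.

* **Separation fallback.** Low-volume windows can separate (for example a
  rare factor perfectly predicting death). The fit then falls back to a
  Newton solver with a small L2 penalty (λ = 1 per coefficient, intercept
  unpenalised), flagged `stabilized=True` on the model. Stabilise-and-flag
  was chosen over failing because early-window coefficient instability is an
  expected feature of this design, not an error.
* **Clipping.** Predictions are clipped to [1e-6, 1 − 1e-6]; the SPRT weight
  is finite only for p < 1.
* **Covariate coding.** Age enters linearly; ejection fraction below 40% is
  coded as two indicators (30–39, and <30-or-missing pooled); MI timing and
  surgical status carry their clinically standard reference levels
  (none/older MI, elective). No interactions or selection.

## Hierarchical gold standard

The profiling comparator models
`O_ij ~ Bernoulli(inv-logit(x_ij'β + φ_j))` with `φ_j ~ Normal(μ, τ²)`.
Priors are weakly informative: Normal(0, 10²) on each coefficient and on μ,
Half-Normal(1) on τ. Covariates are mean-centred before sampling so μ is the
population-average log-odds at the average case mix and mixes independently
of β.

**Sampler.** Adaptive Metropolis-within-Gibbs, fully seeded:

* β updates alternate a covariance-shaped random walk with an independence
  proposal (multivariate normal with the pooled-MLE covariance, inflated
  ×1.1, recentred on the running mean of the first half of burn-in). The
  independence kernel gives near-iid jumps when the posterior is close to
  the pooled MLE — the usual case here — while the random walk guards the
  rare case it is not.
* φ_j updates are independent per-hospital random walks, vectorised across
  hospitals.
* μ has a conjugate Gibbs draw; τ uses a log-scale random walk run three
  times per sweep (it touches only the J hospital effects, and the
  between-hospital scale is the slowest-mixing quantity).
* Proposal scales adapt toward 30% (β) / 44% (scalar) acceptance during
  burn-in only.

Defaults are 3 chains × 2,000 burn-in + 5,000 kept draws; convergence is
declared when split-chain R-hat (via arviz) is below 1.05 for μ, τ and every
β, and a failed check flags the result rather than erroring. Tests and the
acceptance script use smaller, stated budgets (2 chains, 400–1,500 burn-in,
800–2,500 kept) — adequate for the quantities they check, as their own
R-hat values show.

**Risk-standardised rates.** For each retained draw, a hospital's predicted
deaths (its own intercept φ_j) are divided by its expected deaths (the
population-average intercept μ) over its observed case mix, then multiplied
by the statewide unadjusted mortality rate; the per-draw rates are
summarised by the posterior mean and the 2.5th/97.5th percentiles. The rate
scale (not a ratio scale) is used for the interval rule, matching a
reporting convention in which the interval is compared with the statewide
unadjusted rate. The standardisation formula itself is this package's
documented interpretation of "risk-standardised mortality rate"; the source
description does not print one.

**Cross-validation rule.** For hospital *j*, the model is refit without it;
for each retained draw a fresh effect `φ* ~ Normal(μ, τ²)` is drawn (no
information from hospital *j*) and deaths are simulated at the hospital's
observed case mix. The posterior predictive p-value is the fraction of
predictive draws with at least the observed death count (ties count, so zero
observed deaths gives p = 1). A hospital-period is an outlier if the
interval rule fires or p ≤ 0.01; when both fire, the interval rule is
recorded first.

## Synthetic registry

The generator emulates the published registry's marginal structure: 13
hospitals in the first calendar year and 14 thereafter; per-period volumes
4604/4393/3986/3885/3684/3396 with 925 overlap-quarter cases generated once
and assigned to both CY2005 and FY2006; per-period crude mortality targets
2.17/2.25/2.01/1.65/1.41/1.47%; and published marginal risk-factor
prevalences (the earliest year's column is used for every year, for
simplicity; per-year drift is configurable but its realism is not claimed).
Cases are generated on disjoint timeline segments with dates uniform within
each segment and volumes split evenly across active hospitals.

* **Outcome model.** `logit P(death) = c + x'β_true + u_j + Σ ln m`, with a
  per-segment intercept `c` solved (Brent's method) so the expected
  mortality over the drawn case mix — with hospital effects and injections
  excluded — equals the segment target; fixed, documented true coefficients
  `β_true` (clinically plausible magnitudes such as +1.8 log-odds for
  cardiogenic shock and +0.05/year for age; these are recovery targets for
  the tests, not published estimates); optional per-hospital offsets `u_j`;
  and injected odds-ratio multipliers `m` applied to every case of a named
  hospital whose date falls in the named reporting period. Injections are
  multiplicative on the odds, matching the alternative-hypothesis form the
  sequential test is powered against.
* **Independence.** Risk factors are drawn independently from their
  marginals (only marginals are published); age is Normal(66.5, 10.7²)
  truncated to [18, 100]. Real registries have correlated risk factors
  (shock with emergent status, for instance), so passing tests here show
  correct behaviour under the published marginal structure, not robustness
  to real-world correlation, coding drift, or data-quality artifacts.
* **Reproducibility.** One `numpy` Generator seeded from the scenario drives
  everything; identical scenario + seed gives a byte-identical registry.

## Evaluation

The unit is the hospital-period. Sensitivity and specificity are reported as
percentages rounded half-up to one decimal. The published verdict fixture
(`rasprt.reference`) encodes the reported outlier/alert lists; its
as-evaluated table carries 85 units — the 83 unique hospital-periods plus
two overlap-quarter re-evaluation units for the two outlier hospitals,
negative in both sources — because the published accuracy arithmetic uses
5 positives and 80 negatives, which no partition of the 83 unique units
reproduces. Both counts are exposed rather than silently reconciled.

## Problem sizes and numerical choices

Tests and the acceptance script use stated, seeded problem sizes: 20,000
cases for coefficient recovery (each fitted coefficient within 3 reported
SEs of truth); an injected OR = 3 hospital with 600 cases/year at ~2%
baseline for seeded detection; 500 replicates × 400 cases for null
false-alert calibration; 20 replicates for cross-validation p-value
uniformity. At 600 cases/year, an OR = 3 outlier is essentially always
caught by the cross-validation rule, while the interval rule — more
conservative under hierarchical shrinkage — can miss an unlucky draw; the
combined (disjunctive) verdict is the stable quantity.

Other numerics: trajectory exports carry 12 significant digits and
round-trip to that precision; monthly refits are deterministic to 10+
significant digits (IRLS with fixed data); within-day case order is broken
by case id so trajectories are reproducible; a fitted coefficient magnitude
above 15 on the log-odds scale is treated as separation.

## Known limitations

* The hierarchical sampler is tailored to this model family (logistic, one
  random intercept); it is not a general-purpose MCMC engine.
* The cross-validation p-value inherits Monte-Carlo error from the
  predictive simulation (~1/√draws); near the 0.01 threshold this matters,
  and more kept draws are the remedy.
* Surveillance is one-sided (elevated odds only); lower-than-expected
  mortality is out of scope, as is surgeon-level profiling.
* The synthetic registry cannot validate data-quality behaviour (missing
  fields beyond the pooled ejection-fraction level, adjudication effects,
  submission lags) because it never generates such defects.
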