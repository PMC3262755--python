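# rasprt

Risk-adjusted sequential probability ratio testing (RA-SPRT) for hospital
outcome surveillance, with the Bayesian hierarchical profiling "gold
standard" it is evaluated against and a synthetic clinical-registry
simulator that makes the whole evaluation reproducible without any
restricted data.

## The problem

Statewide cardiac-surgery registries publicly report each hospital's
risk-adjusted 30-day mortality, but the rigorous adjudication behind a
public report delays it by one to three years. A sequential control chart
that re-evaluates the evidence after *every case* can warn a hospital of a
developing quality problem far earlier. This package implements that chart
and the machinery to ask the key question: does the fast sequential method
reach the same verdicts as the slow hierarchical public-report analysis?

## The method

For each hospital, cases are analysed in procedure-date order. Case *i*
with model-predicted death probability *p\_i* and observed outcome
*O\_i* ∈ {0,1} updates a cumulative log-likelihood-ratio statistic

```
T_i = T_{i−1} + (O_i − s_i),        s_i = ln((1 − p_i) + OR·p_i) / ln(OR)
```

which starts at 0 and is compared with the Wald boundaries

```
h1 = ln((1 − β)/α) / ln(OR)         h0 = ln(β/(1 − α)) / ln(OR)
```

Crossing h1 accepts the hypothesis that the hospital's odds of death are at
least `OR` times expectation (an **alert**); crossing h0 accepts the null.
The statistic resets to 0 at each reporting-period boundary so verdicts
align with annual public reports. Risk adjustment comes from standard
logistic models refit each month on the prior 11 months of statewide data.

The gold standard is a Bayesian hierarchical logistic regression
(hospital-specific intercepts φ\_j ~ Normal(μ, τ²), fit by MCMC): a
hospital-period is an outlier when the lower limit of the 95% posterior
interval of its risk-standardised mortality rate exceeds the statewide
unadjusted rate, or its leave-one-hospital-out posterior predictive p-value
is 0.01 or smaller. `docs/methods.md` has the full model and design notes.

## Worked example

`examples/02_sprt_control_chart.py` simulates one year of a 14-hospital
registry (600 cases per hospital, ~2% mortality) with one hospital's odds
of death tripled, refits the monthly risk models and runs the chart:

```
decision boundaries: h1 = 4.169925 (alert), h0 = -3.247928

H09: 553 cases analysed, final T = +1.715 -> ALERT
    crossed h1 at case 75 (2004-03-21), T = +4.276
    crossed h1 at case 440 (2004-10-27), T = +4.522
H06: 542 cases analysed, final T = -0.987 -> in control
    crossed h0 at case 506 (2004-12-06), T = -3.269
```

The injected hospital (H09) crosses the alert boundary after 75 cases — in
March of the surveillance year, long before any annual report could exist —
while an unremarkable hospital (H06) drifts down and accepts the null.
(Cases in the first study month are unscored: they train the first model.)

The other examples cover the registry simulator
(`01_simulate_registry.py`), the hierarchical gold standard with both
outlier rules (`03_gold_standard.py`) and the end-to-end replay plus the
published-verdict confusion arithmetic (`04_replay_evaluation.py`), which
prints:

```
published verdict lists:
  TP=5 FP=1 TN=79 FN=0 over 85 hospital-year units
  sensitivity 100.0%  specificity 98.8%
```

i.e. over the 2002–2007 evaluation the sequential method caught all five
published outlier hospital-years and raised one false alert.

A thin CLI mirrors the library (`rasprt simulate | fit-models | run-sprt |
run-gold | evaluate | replay`); run `rasprt --help`.

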