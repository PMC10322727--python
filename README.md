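# ccbias

Complete-case bias and multiple imputation for dichotomised continuous
outcomes under outcome-dependent (MNAR) missingness.

## The problem

Many binary outcomes in epidemiology — depression diagnoses, type-II diabetes,
hypertension — are thresholded versions of an underlying continuous measure.
Logistic regression of a binary outcome *D* on a binary exposure *X* is
famously robust to missingness that depends on the outcome: the exposure odds
ratio from a complete-case analysis is unbiased unless the probability of
being a complete case depends on exposure and outcome jointly (a
multiplicative interaction). That robustness quietly assumes missingness acts
on *D* itself. When non-response instead tracks the underlying continuum —
people with more severe symptoms are less likely to return a questionnaire,
whatever side of the diagnostic threshold they are on — the complete-case
odds ratio is biased, and the bias can be large when the exposure modifies
the association between the continuum and response.

`ccbias` quantifies this bias analytically and by simulation, and evaluates
how much of it multiple imputation (MI) removes when the imputation model
borrows a misclassified proxy of the outcome (for example, a routinely
collected health-record indicator with known sensitivity and specificity).

## The model

The data-generating law is a latent-variable selection model:

- exposure X ~ Bernoulli(π_X), default π_X = 0.25;
- continuous score Y | X = x ~ N(δx, 1), δ calibrated;
- binary outcome D = 1{Y > c} (or P(D=1|Y=y) = expit(α + βy)), with c (or α)
  and δ calibrated so that P(D=1) = 0.15 and the full-population exposure log
  odds ratio is 0.405 (OR 1.50);
- proxy A | D with sensitivity P(A=1|D=1) ∈ {0.25, 0.75} and specificity
  P(A=0|D=0) = 0.975, optionally missing completely at random;
- observation R of (Y, D) with P(R=1|Y=y, X=x) =
  expit(γ₀ + γ_x x + γ_y y + γ_xy xy) (logit or log link).

The complete-case exposure log OR is computed exactly by one-dimensional
quadrature from

    P(D=1 | X=x, R=1) = ∫ P(D=1|y) π(y,x) φ(y−δx) dy / ∫ π(y,x) φ(y−δx) dy,

and compared against the full-population value; the simulation layer
generates cohorts from the same law, imposes the missingness, and runs
complete-case and MI analyses (chained equations, proper draws, Rubin's
rules with fraction of missing information).

## Worked example

Analytic bias of the complete-case log OR when observation odds fall by 25%
per SD of the score (no interaction):

```python
>>> import dataclasses
>>> from ccbias import (default_population, default_missingness,
...                     solve_missingness_intercept, complete_case_log_or)
>>> pop = default_population()          # prev 15%, log OR 0.405, pi_x 0.25
>>> miss = default_missingness(gy_or=0.75)
>>> g0 = solve_missingness_intercept(pop, miss, 0.6)   # 40% missing
>>> res = complete_case_log_or(pop, dataclasses.replace(miss, g0=g0))
>>> round(res.log_or_cc, 6), round(res.percent_bias, 2)
(0.413485, 2.1)
```

The complete-case analysis targets 0.4135 instead of 0.405 — a 2.1% upward
bias at 40% missing outcome data. With the exposure–score interaction turned
on (`default_missingness(interaction=True)`) the same computation gives
+58% bias at 40% missing.

The full factorial study (20 scenarios; complete-case and MI summaries with
bias, empirical SE, Monte Carlo error, mean FMI and precision gain per
scenario):

```
ccbias run-study --out results.csv          # desk scale: 200 reps, m=20
ccbias run-study --paper-scale --out results.csv
ccbias analytic-bias --gy-or 0.9,0.75,0.5 --missing 0.2,0.4,0.6,0.8
ccbias table3-check
```

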