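# Methods

## Data-generating model

A cohort of n subjects is generated as

- exposure X ~ Bernoulli(π_X) with π_X = 0.25 by default;
- continuous outcome score Y | X = x ~ N(μ_x, 1) with μ₀ = 0 and
  μ₁ = δ — a pure location shift, conditional SD fixed at 1, so all
  missingness coefficients are interpretable per SD of the score;
- binary outcome D from Y via a dichotomisation rule: either the hard
  threshold D = 1{Y > c} (default, matching how diagnostic cutoffs act on a
  symptom score) or a logistic link P(D=1|Y=y) = expit(α + βy) with β > 0
  (default β = 3 when selected).  The threshold rule is the β→∞ limit of the
  logistic one; both are supported in every computation and the two agree to
  10⁻³ on all outputs by β = 50;
- proxy A | D with sensitivity P(A=1|D=1) and specificity P(A=0|D=0)
  (defaults 0.75 and 0.975).  A is conditionally independent of X given D,
  which has a useful consequence: logit P(D=1|X,A) is exactly additive in X
  and A, so the main-effects imputation model is correctly specified.

### Calibration

The generator is parameterised by targets, not raw coefficients: marginal
outcome prevalence P(D=1) = 0.15 and full-population exposure log OR 0.405.
`calibrate_dichotomisation` inverts these by nested bracketed root-finding
(Brent, tolerance 10⁻¹²): the inner solve finds the rule location (c or α)
for the prevalence at a trial δ, the outer solve finds δ for the log OR.
For the default targets this gives c = 1.09734, δ = 0.22409.

## Selection (missingness) model

The outcome — both Y and D — is observed with probability
π(y, x) = linkinv(γ₀ + γ_x x + γ_y y + γ_xy xy), logit link by default.  The
log link is also available; because exp of an unbounded linear predictor can
exceed 1, log-link probabilities are capped at 1 (logged at DEBUG).  Exposure
and proxy are always observed; proxy missingness, when enabled, is imposed
completely at random (the simplest mechanism consistent with a stated
missingness fraction; a config hook, not a claim about real linkage data).

Two mechanisms are studied:

1. **Score-only**: γ_x = γ_xy = 0, exp(γ_y) = 0.75 — observation odds fall
   25% per SD of the score.
2. **Interaction**: exp(γ_y) = 0.75 in the unexposed arm and
   exp(γ_y + γ_xy) = 1.0 in the exposed arm (γ_xy = −γ_y).  The magnitudes
   here are this package's choice: the interaction design it emulates is
   qualitative, and these defaults were chosen once to produce substantial
   upward bias (analytically +30% to +111% over the 20–80% missing grid)
   while keeping every fit well-behaved.  They are exposed in the
   configuration, not hard-coded.

The intercept γ₀ is never set directly: `solve_missingness_intercept` finds
the root of the marginal observation probability (a quadrature integral) at
the scenario's target missing fraction, to 10⁻⁸.

## Analytic complete-case odds ratio

With D ⟂ R | (Y, X),

    P(D=1 | X=x, R=1) = ∫ P(D=1|y) π(y,x) φ(y−μ_x) dy
                        / ∫ π(y,x) φ(y−μ_x) dy,

computed by adaptive quadrature truncated at ±14 conditional SDs (results
are invariant to doubling the range; the Gaussian weight kills the tails).
Integrand kinks — the threshold c, steep sigmoid midpoints — are passed to
the quadrature as interval break points so the adaptive rule never straddles
them.  Known closed-form behaviour is preserved exactly: if π depends only
on x, or factorises multiplicatively over x and the *binary* outcome, the
complete-case log OR equals the full-population one (verified to 10⁻⁶).

A property worth recording: the absolute percent bias is monotone increasing
in the missing-data fraction for every association strength on the study
grid, and monotone in the strength of the score–observation association from
40% missing upward — but *not* at 20% missing, where a strong association
(observation OR 0.5/SD) produces less bias than a moderate one (0.75/SD) and
a very strong one (0.25/SD) flips the sign.  Both the quadrature and an
independent large-sample Monte Carlo agree on this inversion; tests assert
the orderings only where they hold.

## Estimation

**Complete-case**: logistic regression of D on X among R = 1.

**Logistic fitter**: Newton–Raphson with observed-information Wald SEs,
convergence at score sup-norm < 10⁻⁸, step-halving for large proposed steps,
and explicit separation detection (diverging coefficients are flagged, never
returned silently).  When every design column is binary — always true here —
the data are first collapsed to covariate-pattern cells and fitted as
grouped binomial counts, which yields the identical MLE and information at a
cost independent of cohort size; the suite cross-checks coefficients and SEs
against statsmodels GLM to 10⁻⁶ on both grouped and ungrouped paths.  The
simulation study performs on the order of 10⁵–10⁶ fits, which is why the
fitter is written directly on NumPy rather than delegating each fit.

**Multiple imputation**: missing D is imputed from (X, A) by proper draws —
the imputation model is fitted on records with D observed, a parameter
vector is drawn from N(MLE, inverse observed information), and missing
values are filled as Bernoulli at the drawn-parameter probabilities (a
bootstrap-refit draw is selectable).  When A is partially missing, chained
equations alternate A | (X, D) and D | (X, A) for a burn-in of 20 cycles
(initialised from the observed marginals) before emitting the completed
pair.  m = 100 imputations at full scale, m = 20 at desk scale.

**Pooling**: Rubin's rules — q̄ the mean estimate, W the mean squared SE, B
the between-imputation variance (denominator m−1), T = W + (1+1/m)B,
df = (m−1)(1 + W/((1+1/m)B))², and the df-adjusted fraction of missing
information FMI = (r̃ + 2/(df+3))/(r̃+1) with r̃ = (1+1/m)B/W; the simple
(B + B/m)/T variant is reported alongside.  B = 0 maps to FMI = 0.

Replicates whose fits separate or fail to converge are flagged, excluded,
and counted; scenario summaries carry the exclusion rate (zero in all shipped
configurations).

## Simulation study design

Four factors: fraction of missing outcome data (0.2/0.4/0.6/0.8), proxy
sensitivity (0.25/0.75), interaction in the selection model (no/yes), and
fraction of missing proxy (0/0.25).  The first three are fully crossed with
a fully observed proxy; the missing-proxy level is run only at the
interaction / sensitivity-0.75 corner, varying the missing-outcome fraction
— 20 scenarios.  Cohorts of n = 10,000; 1,000 replicates and m = 100 at full
scale.  The shipped default is the desk scale, n_sim = 200 and m = 20, which
preserves every qualitative ordering (bias growing with missingness; larger
MI bias reduction and lower FMI at sensitivity 0.75; missing-proxy scenarios
intermediate) at a few minutes of runtime; `--paper-scale` restores the full
design.

Per-scenario metrics: mean log OR, bias (mean − truth), percent bias,
empirical SE (sample SD, denominator n−1), Monte Carlo error
(empirical SE/√n_sim), mean FMI, and the precision gain of MI over the
complete-case analysis, 100·(SE_cc/SE_mi − 1) on the empirical SEs.

## Reproducibility

Every stochastic stage draws from a dedicated counter-based stream seeded by
(base seed, replicate index, stage tag) with stage tags cohort=0,
missingness=1, proxy-missingness=2, imputation=3.  Any stage can be re-run
in isolation; identical configuration and seed give byte-identical results
CSVs, and replicates are independent by construction so concurrent execution
cannot change results.

## What the synthetic cohorts do and do not emulate

The generator reproduces the marginal structure of the motivating cohort
analysis — exposure prevalence, outcome prevalence, effect size, proxy
accuracy — but not its covariates (no confounders are simulated, so no
adjusted models are fitted), not missingness in the exposure or covariates,
and not the clustering or linkage-consent structure of real record linkage.
Conclusions about MI here therefore speak to the outcome-missingness
mechanism in isolation; with partially observed covariates the relative
performance of MI and complete-case analysis can differ.

## Numerical choices

- Quadrature: adaptive, absolute tolerance 10⁻¹² per integral, range ±14 SD,
  explicit break points at integrand kinks.
- Root finding: bracketed Brent, xtol 10⁻¹²; calibration residuals < 10⁻⁸.
- Logistic convergence: score sup-norm < 10⁻⁸, max 40 iterations,
  |coefficient| > 35 treated as separation.
- Percent bias is reported on the log-OR scale; percent rendering of
  diagnostic accuracy uses half-up rounding to 1 decimal, with raw
  proportions always available.

## Known limitations

- The interaction-mechanism coefficient magnitudes are package defaults, not
  estimates; absolute bias values under that mechanism are
  configuration-dependent and only orderings are asserted.
- The log-link selection model caps probabilities at 1 rather than refusing
  saturated configurations.
- No coverage or CI-width metrics; no predictive-mean matching, multilevel
  imputation, or sensitivity-parameter (δ-adjusted) MNAR imputation.
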