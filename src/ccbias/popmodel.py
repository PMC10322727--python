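"""Analytic bias of the complete-case exposure odds ratio under a dichotomised
continuous outcome.

The data-generating law is a latent-variable one: a binary exposure :math:`X`
with prevalence :math:`\\pi_X`, a continuous score :math:`Y \\mid X=x \\sim
N(\\mu_x, 1)`, and a binary outcome :math:`D` produced from :math:`Y` either by
a hard threshold (:math:`D = 1\\{Y > c\\}`) or through a logistic link
(:math:`P(D=1 \\mid Y=y) = \\operatorname{expit}(\\alpha + \\beta y)`).
Missingness acts on the *continuous* score: the probability that the outcome is
observed is :math:`\\pi(y, x) = g^{-1}(\\gamma_0 + \\gamma_x x + \\gamma_y y +
\\gamma_{xy} x y)` with a logit or log link.  Because selection operates on
:math:`Y` rather than on :math:`D` directly, the usual robustness of the
logistic-regression odds ratio to outcome-dependent missingness breaks down,
and the complete-case log OR

.. math::

    \\log\\mathrm{OR}_{cc}
      = \\operatorname{logit} P(D=1 \\mid X=1, R=1)
      - \\operatorname{logit} P(D=1 \\mid X=0, R=1),
    \\qquad
    P(D=1 \\mid X=x, R=1)
      = \\frac{\\int P(D=1\\mid y)\\,\\pi(y,x)\\,\\phi(y-\\mu_x)\\,dy}
             {\\int \\pi(y,x)\\,\\phi(y-\\mu_x)\\,dy},

differs from the full-population log OR.  Everything here is one-dimensional
adaptive quadrature plus bracketed root finding; no simulation is involved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

logger = logging.getLogger("ccbias")

# Quadrature / root-finding tolerances used throughout the analytic layer.
QUAD_EPSABS = 1e-12
ROOT_XTOL = 1e-12
# Integration half-width in conditional SD units; integrals are insensitive to
# doubling this (the Gaussian weight kills the tails).
QUAD_RANGE = 14.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DichotomisationRule:
    """How the binary outcome D is produced from the continuous score Y.

    kind="threshold": D = 1{Y > c} (the beta -> infinity limit of the logistic
    kind).  kind="logistic": P(D=1|Y=y) = expit(alpha + beta*y), beta > 0 so a
    higher score means a higher chance of being a case.
    """

    kind: Literal["threshold", "logistic"] = "threshold"
    c: float = 0.0
    alpha: float = 0.0
    beta: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("threshold", "logistic"):
            raise ValueError(f"unknown dichotomisation kind {self.kind!r}")
        if self.kind == "logistic" and not self.beta > 0:
            raise ValueError("logistic dichotomisation requires beta > 0")
        for name in ("c", "alpha", "beta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite dichotomisation parameter {name}")

    def case_prob_given_y(self, y):
        """P(D=1 | Y=y), vectorised over y."""
        y = np.asarray(y, dtype=float)
        if self.kind == "threshold":
            return (y > self.c).astype(float)
        return expit(self.alpha + self.beta * y)


@dataclass(frozen=True)
class PopulationModel:
    """Latent-outcome data-generating law.

    pi_x is the exposure prevalence; mu0/mu1 are the conditional means of the
    continuous score given X=0/1 (conditional SD fixed at 1, so mu1 - mu0 is
    the exposure effect in SD units).
    """

    pi_x: float
    mu0: float
    mu1: float
    dicho: DichotomisationRule

    def __post_init__(self) -> None:
        if not (0.0 < self.pi_x < 1.0):
            raise ValueError("pi_x must lie strictly between 0 and 1")
        if not (math.isfinite(self.mu0) and math.isfinite(self.mu1)):
            raise ValueError("conditional means must be finite")

    @property
    def delta(self) -> float:
        """Exposure shift of the continuous score, mu1 - mu0."""
        return self.mu1 - self.mu0

    def mu(self, x: int) -> float:
        return self.mu1 if x else self.mu0


@dataclass(frozen=True)
class MissingnessModel:
    """Selection model for the probability that the outcome is observed.

    pi(y, x) = linkinv(g0 + gx*x + gy*y + gxy*x*y).  With the log link the
    linear predictor can exceed 0 on an unbounded y; probabilities are then
    capped at 1 (logged once per model evaluation batch).
    """

    link: Literal["logit", "log"] = "logit"
    g0: float = 0.0
    gx: float = 0.0
    gy: float = 0.0
    gxy: float = 0.0

    def __post_init__(self) -> None:
        if self.link not in ("logit", "log"):
            raise ValueError(f"unknown missingness link {self.link!r}")
        for name in ("g0", "gx", "gy", "gxy"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite missingness parameter {name}")

    @property
    def is_mcar(self) -> bool:
        return self.gx == self.gy == self.gxy == 0.0

    def observe_prob(self, y, x):
        """pi(y, x) = P(R=1 | Y=y, X=x), vectorised; log link capped at 1."""
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        lin = self.g0 + self.gx * x + self.gy * y + self.gxy * x * y
        if self.link == "logit":
            return expit(lin)
        p = np.exp(lin)
        if np.any(p > 1.0):
            logger.debug("log-link observation probability capped at 1")
        return np.minimum(p, 1.0)


@dataclass(frozen=True)
class BinaryMissingnessModel:
    """Selection acting on the *binary* outcome: pi(d, x) = a_x[x] * b_d[d].

    The classical robustness setting: when the probability of being a complete
    case factorises over exposure and the binary outcome (no interaction on
    the multiplicative scale), the complete-case odds ratio is unbiased.  Used
    to contrast with the latent-score selection of MissingnessModel.
    """

    a0: float = 1.0
    a1: float = 1.0
    b0: float = 1.0
    b1: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a0", "a1", "b0", "b1"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")

    def observe_prob(self, d, x):
        d = np.asarray(d)
        x = np.asarray(x)
        return np.where(x == 1, self.a1, self.a0) * np.where(d == 1, self.b1, self.b0)


@dataclass(frozen=True)
class BiasResult:
    """Full-population vs complete-case exposure log OR and their gap."""

    log_or_full: float
    log_or_cc: float
    frac_observed: float

    @property
    def bias(self) -> float:
        return self.log_or_cc - self.log_or_full

    @property
    def percent_bias(self) -> float:
        if self.log_or_full == 0.0:
            raise ZeroDivisionError("percent bias undefined for a null full-population log OR")
        return 100.0 * self.bias / self.log_or_full


# ---------------------------------------------------------------------------
# integrals
# ---------------------------------------------------------------------------

def _quad_gauss(f, mu: float, *, splits: Sequence[float] = ()) -> float:
    """Integrate f(y)*phi(y - mu) over the real line (truncated at QUAD_RANGE).

    splits mark integrand kinks (the dichotomisation threshold, steep sigmoid
    midpoints) so the adaptive rule never straddles them.
    """
    lo, hi = mu - QUAD_RANGE, mu + QUAD_RANGE
    def g(y):
        return f(y) * norm.pdf(y - mu)
    knots = [lo] + sorted(s for s in splits if lo < s < hi) + [hi]
    return sum(quad(g, a, b, epsabs=QUAD_EPSABS, limit=200)[0]
               for a, b in zip(knots[:-1], knots[1:]))


def _dicho_splits(rule: DichotomisationRule) -> list[float]:
    """Integrand knots introduced by the dichotomisation rule."""
    if rule.kind == "threshold":
        return [rule.c]
    return [-rule.alpha / rule.beta]  # sigmoid midpoint (matters when steep)


def case_prob(model: PopulationModel, x: int) -> float:
    """P(D=1 | X=x): closed form for the threshold rule, quadrature otherwise."""
    mu = model.mu(x)
    rule = model.dicho
    if rule.kind == "threshold":
        return float(norm.sf(rule.c - mu))
    p = _quad_gauss(rule.case_prob_given_y, mu, splits=_dicho_splits(rule))
    return float(min(max(p, 0.0), 1.0))


def full_population_log_or(model: PopulationModel) -> float:
    """Exposure log odds ratio in the full population."""
    p0, p1 = case_prob(model, 0), case_prob(model, 1)
    for p in (p0, p1):
        if not (0.0 < p < 1.0):
            raise ValueError("degenerate dichotomisation: case probability is 0 or 1")
    return float(logit(p1) - logit(p0))


def marginal_case_prev(model: PopulationModel) -> float:
    """Marginal P(D=1) = (1-pi_x)*p0 + pi_x*p1."""
    return (1.0 - model.pi_x) * case_prob(model, 0) + model.pi_x * case_prob(model, 1)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_dichotomisation(
    target_prev: float,
    target_log_or: float,
    pi_x: float,
    kind: Literal["threshold", "logistic"] = "threshold",
    beta: float = 3.0,
) -> tuple[DichotomisationRule, float]:
    """Invert (marginal prevalence, full-population log OR) for the generator.

    Solves for the rule location (threshold c, or logistic intercept alpha)
    and the exposure shift delta = mu1 - mu0 (mu0 fixed at 0) so that the
    marginal case prevalence equals ``target_prev`` and the full-population
    exposure log OR equals ``target_log_or``.  Nested bracketed root finding:
    for each trial delta the location parameter is re-solved for the
    prevalence (monotone), and the outer bracket is on delta for the log OR
    (monotone for beta > 0).

    Returns (rule, delta); residuals are below 1e-8 by construction.
    """
    if not (0.0 < target_prev < 1.0):
        raise ValueError("target_prev must lie strictly between 0 and 1")
    if not math.isfinite(target_log_or):
        raise ValueError("target_log_or must be finite")

    def model_for(loc: float, delta: float) -> PopulationModel:
        if kind == "threshold":
            rule = DichotomisationRule(kind="threshold", c=loc)
        else:
            rule = DichotomisationRule(kind="logistic", alpha=loc, beta=beta)
        return PopulationModel(pi_x=pi_x, mu0=0.0, mu1=delta, dicho=rule)

    # location bracket: threshold c directly, or alpha = -beta * c_effective
    loc_lo, loc_hi = (-15.0, 15.0) if kind == "threshold" else (-15.0 * beta, 15.0 * beta)

    def loc_for_delta(delta: float) -> float:
        # prevalence decreases in c but increases in alpha; brentq handles both
        return brentq(
            lambda loc: marginal_case_prev(model_for(loc, delta)) - target_prev,
            loc_lo, loc_hi, xtol=ROOT_XTOL,
        )

    def lor_resid(delta: float) -> float:
        return full_population_log_or(model_for(loc_for_delta(delta), delta)) - target_log_or

    if target_log_or == 0.0:
        delta = 0.0
    else:
        bound = math.copysign(1.0, target_log_or)
        # expand the delta bracket until the residual changes sign
        for _ in range(20):
            if lor_resid(bound) * math.copysign(1.0, target_log_or) >= 0:
                break
            bound *= 2.0
        else:
            raise RuntimeError("no solution for delta in search bracket")
        delta = brentq(lor_resid, min(0.0, bound), max(0.0, bound), xtol=ROOT_XTOL)
    loc = loc_for_delta(delta)
    if kind == "threshold":
        rule = DichotomisationRule(kind="threshold", c=loc)
    else:
        rule = DichotomisationRule(kind="logistic", alpha=loc, beta=beta)
    return rule, float(delta)


def default_population(
    prev: float = 0.15,
    log_or: float = 0.405,
    pi_x: float = 0.25,
    kind: Literal["threshold", "logistic"] = "threshold",
    beta: float = 3.0,
) -> PopulationModel:
    """The calibrated default cohort law: exposure prevalence 25%, outcome
    prevalence 15%, exposure log OR 0.405 (OR 1.50)."""
    rule, delta = calibrate_dichotomisation(prev, log_or, pi_x, kind=kind, beta=beta)
    return PopulationModel(pi_x=pi_x, mu0=0.0, mu1=delta, dicho=rule)


# ---------------------------------------------------------------------------
# complete-case odds ratio
# ---------------------------------------------------------------------------

def _cc_case_prob(model: PopulationModel, miss: MissingnessModel, x: int) -> float:
    """P(D=1 | X=x, R=1) by ratio of quadratures (D independent of R given Y, X)."""
    mu = model.mu(x)
    rule = model.dicho
    splits = _dicho_splits(rule)

    def pi_y(y):
        return miss.observe_prob(y, x)

    def num_f(y):
        return rule.case_prob_given_y(y) * pi_y(y)

    den = _quad_gauss(pi_y, mu, splits=splits)
    if den < 1e-300:
        raise FloatingPointError("observation probability integrates to ~0: no complete cases")
    num = _quad_gauss(num_f, mu, splits=splits)
    return float(min(max(num / den, 0.0), 1.0))


def frac_observed(model: PopulationModel, miss: MissingnessModel) -> float:
    """Marginal probability of the outcome being observed."""
    tot = 0.0
    for x, w in ((0, 1.0 - model.pi_x), (1, model.pi_x)):
        tot += w * _quad_gauss(lambda y: miss.observe_prob(y, x), model.mu(x))
    return float(tot)


def complete_case_log_or(model: PopulationModel, miss: MissingnessModel) -> BiasResult:
    """Analytic complete-case exposure log OR and its bias."""
    lor_full = full_population_log_or(model)
    q0 = _cc_case_prob(model, miss, 0)
    q1 = _cc_case_prob(model, miss, 1)
    for q in (q0, q1):
        if not (0.0 < q < 1.0):
            raise ValueError("complete-case case probability degenerate (0 or 1)")
    return BiasResult(
        log_or_full=lor_full,
        log_or_cc=float(logit(q1) - logit(q0)),
        frac_observed=frac_observed(model, miss),
    )


def complete_case_log_or_binary(
    model: PopulationModel, bmiss: BinaryMissingnessModel
) -> BiasResult:
    """Complete-case log OR when selection acts multiplicatively on (D, X).

    P(D=1 | X=x, R=1) = p_x b1 / (p_x b1 + (1-p_x) b0); the exposure factor
    a_x cancels within each arm and b1/b0 cancels in the odds ratio, so the
    complete-case log OR equals the full-population one.  Computed explicitly
    (not short-circuited) so tests exercise the arithmetic.
    """
    lor_full = full_population_log_or(model)
    qs = []
    fobs = 0.0
    for x, w in ((0, 1.0 - model.pi_x), (1, model.pi_x)):
        p = case_prob(model, x)
        joint1 = p * bmiss.observe_prob(1, x)
        joint0 = (1.0 - p) * bmiss.observe_prob(0, x)
        qs.append(joint1 / (joint1 + joint0))
        fobs += w * (joint1 + joint0)
    return BiasResult(
        log_or_full=lor_full,
        log_or_cc=float(logit(qs[1]) - logit(qs[0])),
        frac_observed=float(fobs),
    )


def solve_missingness_intercept(
    model: PopulationModel,
    miss: MissingnessModel,
    target_frac_observed: float,
) -> float:
    """Intercept g0 making the marginal observation probability hit a target.

    Root of sum_x P(X=x) * E[pi(Y, x)] = target_frac_observed by bracketed
    Brent; the g0 field of ``miss`` is ignored.
    """
    if not (0.0 < target_frac_observed < 1.0):
        raise ValueError("target_frac_observed must lie strictly between 0 and 1")

    def resid(g0: float) -> float:
        return frac_observed(model, replace(miss, g0=g0)) - target_frac_observed

    lo, hi = -40.0, 40.0
    if resid(lo) * resid(hi) > 0:
        raise RuntimeError("no intercept attains the target observed fraction "
                           "(link saturated)")
    return float(brentq(resid, lo, hi, xtol=ROOT_XTOL))


def bias_curve(
    model: PopulationModel,
    gy_grid: Sequence[float],
    missing_grid: Sequence[float],
    link: Literal["logit", "log"] = "logit",
    gx: float = 0.0,
    gxy: float = 0.0,
) -> pd.DataFrame:
    """Analytic percent-bias surface over missingness strength x % missing.

    gy_grid holds observation ORs per 1 SD of the continuous outcome (1.0 is
    MCAR); missing_grid holds fractions of missing outcome data.  The
    intercept g0 is re-solved in every cell.
    """
    if len(gy_grid) == 0 or len(missing_grid) == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for gy_or in gy_grid:
        template = MissingnessModel(link=link, gx=gx, gy=math.log(gy_or), gxy=gxy)
        for frac_missing in missing_grid:
            g0 = solve_missingness_intercept(model, template, 1.0 - frac_missing)
            res = complete_case_log_or(model, replace(template, g0=g0))
            rows.append({
                "gy_or": gy_or,
                "frac_missing": frac_missing,
                "log_or_full": res.log_or_full,
                "log_or_cc": res.log_or_cc,
                "bias": res.bias,
                "percent_bias": res.percent_bias,
                "frac_observed": res.frac_observed,
            })
    return pd.DataFrame(rows)
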