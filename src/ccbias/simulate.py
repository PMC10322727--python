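"""Seeded generation of synthetic cohorts and MNAR masking.

Each cohort emulates a birth-cohort analysis of a binary exposure (maternal
smoking in pregnancy, prevalence 25%) against a binary outcome (offspring
depression, prevalence 15%) that is a dichotomised version of a continuous
symptom score, plus a misclassified record-linkage proxy of the outcome
(configurable sensitivity, specificity 97.5%).  Missingness is imposed on the
outcome only — both the continuous and the binary version — with probability
of observation driven by the *continuous* score (MNAR), optionally interacting
with the exposure.  The proxy may itself carry completely-at-random
missingness.

Cohorts are plain pandas DataFrames with columns

* ``x`` — exposure (0/1, always observed)
* ``y`` — continuous score (NaN where the outcome is missing)
* ``d`` — binary outcome (NaN where missing)
* ``a`` — proxy (NaN where missing)
* ``r`` — outcome-observed indicator (0/1, always observed)

Reproducibility contract: every stochastic stage draws from a dedicated
counter-based stream keyed by (base seed, replicate index, stage tag), so any
stage can be re-run independently and (seed, replicate) fully determines the
cohort and all masks.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from . import tables2x2
from .popmodel import (
    MissingnessModel,
    PopulationModel,
    default_population,
    solve_missingness_intercept,
)

# stage tags of the counter-based seeding scheme
STAGE_COHORT = 0
STAGE_MISSINGNESS = 1
STAGE_AUX_MISSINGNESS = 2
STAGE_IMPUTATION = 3

# Interaction-mechanism default: observation OR per SD of the score is 0.75 in
# the unexposed arm and 1.0 in the exposed arm (gxy = -gy).  The published
# design varies the interaction qualitatively only, so these magnitudes are
# this package's choice, made to produce substantial upward bias.
GY_DEFAULT_OR = 0.75


def rng_stream(base_seed: int, replicate: int, stage: int) -> np.random.Generator:
    """Named stream: (base seed, replicate index, stage tag) -> Generator."""
    return np.random.default_rng(np.random.SeedSequence([base_seed, replicate, stage]))


@dataclass(frozen=True)
class AuxiliaryModel:
    """Misclassification law of the proxy outcome.

    sensitivity = P(A=1 | D=1), specificity = P(A=0 | D=0); frac_missing is
    the completely-at-random share of proxy values masked.
    """

    sensitivity: float = 0.75
    specificity: float = 0.975
    frac_missing: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must lie in [0, 1]")
        if not (0.0 <= self.frac_missing < 1.0):
            raise ValueError("frac_missing must lie in [0, 1)")


def default_missingness(
    interaction: bool = False,
    link: Literal["logit", "log"] = "logit",
    gy_or: float = GY_DEFAULT_OR,
) -> MissingnessModel:
    """Missingness template for the two study mechanisms (intercept unsolved).

    Mechanism (i): observation probability depends only on the continuous
    outcome, OR per SD = ``gy_or``.  Mechanism (ii) (interaction=True):
    additionally an exposure-by-outcome interaction, with the slope cancelled
    in the exposed arm (gxy = -gy).
    """
    gy = math.log(gy_or)
    return MissingnessModel(link=link, g0=0.0, gx=0.0, gy=gy,
                            gxy=-gy if interaction else 0.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial design plus the generator configuration.

    factor1: fraction of missing outcome data (study grid 0.2/0.4/0.6/0.8);
    factor2: proxy sensitivity (0.25 or 0.75); factor3: exposure-outcome
    interaction in the selection model; factor4: fraction of missing proxy
    values.  Defaults n=10,000, n_sim=1,000, m=100 mirror the full-scale
    simulation study.
    """

    factor1: float = 0.4
    factor2: float = 0.75
    factor3: bool = False
    factor4: float = 0.0
    n: int = 10_000
    n_sim: int = 1_000
    m: int = 100
    seed: int = 2023
    specificity: float = 0.975
    population: PopulationModel = None  # type: ignore[assignment]
    missingness: MissingnessModel = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 < self.factor1 < 1.0):
            raise ValueError("factor1 (fraction missing outcome) must lie in (0, 1)")
        if not (0.0 <= self.factor4 < 1.0):
            raise ValueError("factor4 (fraction missing proxy) must lie in [0, 1)")
        if self.n <= 0 or self.n_sim <= 0 or self.m < 2:
            raise ValueError("need n > 0, n_sim > 0, m >= 2")
        if self.population is None:
            object.__setattr__(self, "population", default_population())
        if self.missingness is None:
            object.__setattr__(self, "missingness",
                               default_missingness(interaction=self.factor3))

    @property
    def auxiliary(self) -> AuxiliaryModel:
        return AuxiliaryModel(sensitivity=self.factor2,
                              specificity=self.specificity,
                              frac_missing=self.factor4)

    def solved_missingness(self) -> MissingnessModel:
        """Missingness model with g0 solved for the factor1 observed fraction.

        The quadrature root-find is memoised: every replicate of a scenario
        shares one solve.
        """
        g0 = _solved_intercept(self.population, self.missingness, 1.0 - self.factor1)
        return replace(self.missingness, g0=g0)


@functools.lru_cache(maxsize=256)
def _solved_intercept(population: PopulationModel, missingness: MissingnessModel,
                      target_frac_observed: float) -> float:
    return solve_missingness_intercept(population, missingness, target_frac_observed)


def draw_cohort(spec: ScenarioSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Complete cohort (before any missingness): X, Y|X, D from Y, A from D."""
    pop, aux = spec.population, spec.auxiliary
    n = spec.n
    x = (rng.random(n) < pop.pi_x).astype(np.int64)
    y = np.where(x == 1, pop.mu1, pop.mu0) + rng.standard_normal(n)
    rule = pop.dicho
    if rule.kind == "threshold":
        d = (y > rule.c).astype(np.int64)
    else:
        d = (rng.random(n) < rule.case_prob_given_y(y)).astype(np.int64)
    p_a = np.where(d == 1, aux.sensitivity, 1.0 - aux.specificity)
    a = (rng.random(n) < p_a).astype(np.int64)
    return pd.DataFrame({
        "x": x,
        "y": y,
        "d": d.astype(float),
        "a": a.astype(float),
        "r": np.ones(n, dtype=np.int64),
    })


def impose_missingness(
    cohort: pd.DataFrame, miss: MissingnessModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw R ~ Bernoulli(pi(y, x)) and mask both y and d where R=0."""
    out = cohort.copy()
    pi = np.asarray(miss.observe_prob(out["y"].to_numpy(), out["x"].to_numpy()))
    if np.any((pi < 0.0) | (pi > 1.0)):
        raise ValueError("observation probabilities outside [0, 1]")
    r = (rng.random(len(out)) < pi).astype(np.int64)
    out["r"] = r
    out.loc[r == 0, ["y", "d"]] = np.nan
    return out


def impose_aux_missingness(
    cohort: pd.DataFrame, frac: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Mask each proxy value independently with probability frac (MCAR)."""
    if not (0.0 <= frac < 1.0):
        raise ValueError("frac must lie in [0, 1)")
    out = cohort.copy()
    if frac > 0.0:
        mask = rng.random(len(out)) < frac
        out.loc[mask, "a"] = np.nan
    return out


def simulate_replicate(spec: ScenarioSpec, replicate: int) -> pd.DataFrame:
    """Full pipeline for one replicate: draw, impose outcome and proxy masks."""
    cohort = draw_cohort(spec, rng_stream(spec.seed, replicate, STAGE_COHORT))
    cohort = impose_missingness(cohort, spec.solved_missingness(),
                                rng_stream(spec.seed, replicate, STAGE_MISSINGNESS))
    return impose_aux_missingness(cohort, spec.factor4,
                                  rng_stream(spec.seed, replicate, STAGE_AUX_MISSINGNESS))


def measure_aux_accuracy(cohort: pd.DataFrame) -> tuple[float, float]:
    """Empirical (sensitivity, specificity) of the proxy against the outcome
    on records where both are observed."""
    both = cohort.dropna(subset=["d", "a"])
    if both.empty:
        raise ValueError("no jointly observed (outcome, proxy) pairs")
    d = both["d"].to_numpy().astype(int)
    a = both["a"].to_numpy().astype(int)
    t = tables2x2.TwoByTwo(
        tn=int(np.sum((a == 0) & (d == 0))),
        fp=int(np.sum((a == 1) & (d == 0))),
        fn=int(np.sum((a == 0) & (d == 1))),
        tp=int(np.sum((a == 1) & (d == 1))),
    )
    return tables2x2.sensitivity(t), tables2x2.specificity(t)
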