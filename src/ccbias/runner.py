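"""Factorial scenario orchestration: expand the study design, run every
scenario replicate-by-replicate, and serialise the summaries.

The full-scale design crosses four factors: percent missing outcome data
(20/40/60/80%), proxy sensitivity (25/75%), exposure-outcome interaction in
the selection model (no/yes), and percent missing proxy (0/25%).  All
factor1 x factor2 x factor3 combinations are run with a fully observed proxy;
the missing-proxy level is run only with interaction present and sensitivity
75%, varying factor1 — 20 scenarios in total.  Each scenario is summarised
for the complete-case and the MI estimator.

Determinism: replicate k of scenario s draws all randomness from streams
keyed by (base_seed + s, k, stage), so identical config + seed reproduces the
results byte-for-byte regardless of execution order, and replicates are safe
to run concurrently.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import itertools
import logging
from dataclasses import dataclass

import pandas as pd
import yaml

from . import metrics
from .estimate import complete_case_estimate, mi_estimate
from .popmodel import full_population_log_or
from .simulate import (
    STAGE_IMPUTATION,
    ScenarioSpec,
    default_missingness,
    rng_stream,
    simulate_replicate,
)
from .popmodel import default_population

logger = logging.getLogger("ccbias")

RESULT_COLUMNS = [
    "scenario_id", "factor1", "factor2", "factor3", "factor4", "method",
    "n_sim_used", "mean_log_or", "bias", "percent_bias", "empirical_se",
    "mc_error", "mean_fmi", "precision_gain_pct", "failure_rate",
]


@dataclass(frozen=True)
class StudyDesign:
    scenarios: tuple[ScenarioSpec, ...]
    seed: int
    burn_in: int = 20

    def scenario_id(self, i: int) -> str:
        s = self.scenarios[i]
        return (f"f1={s.factor1:g}|f2={s.factor2:g}|"
                f"f3={'yes' if s.factor3 else 'no'}|f4={s.factor4:g}")


def default_config() -> dict:
    """The shipped study configuration (desk scale; see ``paper.yaml``)."""
    text = importlib.resources.files("ccbias").joinpath("paper.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate_config(cfg: dict) -> dict:
    """Explicit config validation with precise error messages."""
    cfg = {**default_config(), **cfg}
    for key in ("factor1", "factor2", "factor3", "factor4"):
        levels = cfg[key]
        if not isinstance(levels, (list, tuple)) or len(levels) == 0:
            raise ValueError(f"{key} must be a non-empty list of levels")
    if any(not (0.0 < f < 1.0) for f in cfg["factor1"]):
        raise ValueError("factor1 levels must lie in (0, 1)")
    if any(not (0.0 <= f <= 1.0) for f in cfg["factor2"]):
        raise ValueError("factor2 levels must lie in [0, 1]")
    if any(not isinstance(f, bool) for f in cfg["factor3"]):
        raise ValueError("factor3 levels must be booleans")
    if any(not (0.0 <= f < 1.0) for f in cfg["factor4"]):
        raise ValueError("factor4 levels must lie in [0, 1)")
    if cfg.get("strict_paper", True):
        if not cfg.get("factor4_interaction", True):
            raise ValueError("strict-paper mode: missing-proxy scenarios require "
                             "the interaction mechanism (factor3 = yes)")
    for key in ("n", "n_sim", "m", "seed", "burn_in"):
        if int(cfg[key]) != cfg[key] or cfg[key] < 0:
            raise ValueError(f"{key} must be a non-negative integer")
    return cfg


def expand_design(config: dict | None = None) -> StudyDesign:
    """Expand factor grids into the deterministic ordered scenario list.

    Ordering: all (factor3, factor2, factor1) combinations with factor4 = 0
    first (factor3 outer, then factor2, then factor1), then each nonzero
    factor4 level crossed with factor1 at the fixed interaction/sensitivity-75
    corner of the design.
    """
    cfg = _validate_config(config or {})
    pop = default_population(
        prev=cfg["population"]["prev"],
        log_or=cfg["population"]["log_or"],
        pi_x=cfg["population"]["pi_x"],
        kind=cfg["population"]["dicho"],
    )

    def make(f1, f2, f3, f4, idx):
        return ScenarioSpec(
            factor1=f1, factor2=f2, factor3=f3, factor4=f4,
            n=cfg["n"], n_sim=cfg["n_sim"], m=cfg["m"],
            seed=cfg["seed"] + idx, specificity=cfg["specificity"],
            population=pop,
            missingness=default_missingness(interaction=f3, link=cfg["link"],
                                            gy_or=cfg["gy_or"]),
        )

    scenarios = []
    for f3, f2, f1 in itertools.product(cfg["factor3"], cfg["factor2"], cfg["factor1"]):
        scenarios.append(make(f1, f2, f3, 0.0, len(scenarios)))
    f4_f2 = cfg.get("factor4_sensitivity", 0.75)
    f4_f3 = cfg.get("factor4_interaction", True)
    for f4 in cfg["factor4"]:
        if f4 == 0.0:
            continue
        for f1 in cfg["factor1"]:
            scenarios.append(make(f1, f4_f2, f4_f3, f4, len(scenarios)))
    return StudyDesign(scenarios=tuple(scenarios), seed=cfg["seed"],
                       burn_in=cfg["burn_in"])


def run_scenario(spec: ScenarioSpec, burn_in: int = 20,
                 scenario_id: str = "") -> list[dict]:
    """Run one scenario: n_sim replicates, CC and MI summaries."""
    truth = full_population_log_or(spec.population)
    cc_estimates, mi_estimates, fmis = [], [], []
    failures = 0
    for rep in range(spec.n_sim):
        cohort = simulate_replicate(spec, rep)
        try:
            cc = complete_case_estimate(cohort)
            if not cc.converged:
                raise RuntimeError(cc.message)
            pooled = mi_estimate(cohort, spec.m,
                                 rng_stream(spec.seed, rep, STAGE_IMPUTATION),
                                 burn_in=burn_in)
        except (RuntimeError, ValueError) as exc:
            failures += 1
            logger.info("scenario %s replicate %d excluded: %s", scenario_id, rep, exc)
            continue
        cc_estimates.append(cc.estimate)
        mi_estimates.append(pooled.qbar)
        fmis.append(pooled.fmi)
    nan = float("nan")

    def _sum(estimates):
        if len(estimates) >= 2:
            return metrics.summarize(estimates, truth)
        # single replicate: point estimate only, no spread
        est = estimates[0]
        return metrics.ScenarioSummary(
            n_sim_used=1, mean_log_or=est, bias=est - truth,
            percent_bias=100.0 * (est - truth) / truth,
            empirical_se=nan, mc_error=nan)

    cc_sum = _sum(cc_estimates)
    mi_sum = _sum(mi_estimates)
    gain = (metrics.precision_gain(cc_sum.empirical_se, mi_sum.empirical_se)
            if len(cc_estimates) >= 2 else nan)
    base = {
        "scenario_id": scenario_id,
        "factor1": spec.factor1, "factor2": spec.factor2,
        "factor3": spec.factor3, "factor4": spec.factor4,
        "failure_rate": failures / spec.n_sim,
    }
    rows = []
    for method, s in (("cc", cc_sum), ("mi", mi_sum)):
        rows.append({
            **base, "method": method, "n_sim_used": s.n_sim_used,
            "mean_log_or": s.mean_log_or, "bias": s.bias,
            "percent_bias": s.percent_bias, "empirical_se": s.empirical_se,
            "mc_error": s.mc_error,
            "mean_fmi": float(pd.Series(fmis).mean()) if method == "mi" else float("nan"),
            "precision_gain_pct": gain if method == "mi" else float("nan"),
        })
    return rows


def run_study(design: StudyDesign, n_sim_override: int | None = None,
              m_override: int | None = None, out=None) -> pd.DataFrame:
    """Run every scenario of the design and return (optionally write) the
    results table, one row per scenario x method, in design order."""
    rows = []
    for i, spec in enumerate(design.scenarios):
        if n_sim_override is not None:
            spec = dataclasses.replace(spec, n_sim=n_sim_override)
        if m_override is not None:
            spec = dataclasses.replace(spec, m=m_override)
        sid = design.scenario_id(i)
        logger.info("running scenario %s (n_sim=%d, m=%d)", sid, spec.n_sim, spec.m)
        rows.extend(run_scenario(spec, burn_in=design.burn_in, scenario_id=sid))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if out is not None:
        df.to_csv(out, index=False, float_format="%.10g")
    return df


def plot_percent_bias(results: pd.DataFrame, path) -> None:
    """Simple percent-bias chart: one line per (method, sensitivity) against
    the fraction of missing outcome data, faceted by interaction."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    facets = sorted(results["factor3"].unique())
    fig, axes = plt.subplots(1, len(facets), figsize=(5 * len(facets), 4),
                             squeeze=False, sharey=False)
    for ax, f3 in zip(axes[0], facets):
        sub = results[results["factor3"] == f3]
        for (method, f2), grp in sub.groupby(["method", "factor2"]):
            grp = grp.sort_values("factor1")
            truth = float((grp["mean_log_or"] - grp["bias"]).iloc[0])
            ax.errorbar(100 * grp["factor1"], grp["percent_bias"],
                        yerr=1.96 * 100 * grp["mc_error"] / abs(truth),
                        marker="o", capsize=3,
                        label=f"{method.upper()}, sens {100 * f2:g}%")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("% missing outcome data")
        ax.set_ylabel("% bias in log OR")
        ax.set_title(f"interaction: {'yes' if f3 else 'no'}")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
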