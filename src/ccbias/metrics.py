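"""Replicate-level performance metrics for the simulation study.

Conventions follow standard simulation-study reporting: bias is the mean
estimate minus the truth, the empirical SE is the sample standard deviation of
the point estimates (denominator n-1), and the Monte Carlo error of the bias
is empirical SE / sqrt(n_sim).  The precision gain of MI over the
complete-case analysis is the CC-to-MI standard-error ratio minus one,
expressed as a percent (so 24% means the CC standard error is 1.24 times the
MI one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ScenarioSummary:
    n_sim_used: int
    mean_log_or: float
    bias: float
    percent_bias: float
    empirical_se: float
    mc_error: float
    mean_fmi: float | None = None
    precision_gain_pct: float | None = None


def summarize(estimates, truth: float) -> ScenarioSummary:
    """Aggregate replicate log-OR estimates against the known truth."""
    q = np.asarray(estimates, dtype=float)
    if q.size < 2:
        raise ValueError("need at least 2 replicate estimates")
    mean = float(q.mean())
    bias = mean - truth
    if truth == 0.0:
        raise ZeroDivisionError("percent bias undefined for a null truth")
    emp_se = float(q.std(ddof=1))
    return ScenarioSummary(
        n_sim_used=int(q.size),
        mean_log_or=mean,
        bias=bias,
        percent_bias=100.0 * bias / truth,
        empirical_se=emp_se,
        mc_error=emp_se / math.sqrt(q.size),
    )


def error_bar(summary: ScenarioSummary) -> float:
    """Half-width of the bias error bar: 1.96 x Monte Carlo error."""
    return 1.96 * summary.mc_error


def precision_gain(se_cc: float, se_mi: float) -> float:
    """Percent precision increase of MI over CC: 100*(se_cc/se_mi - 1).

    Negative values (a precision loss) are reported as-is, never clipped.
    """
    if not (se_cc > 0.0 and se_mi > 0.0):
        raise ValueError("standard errors must be positive")
    return 100.0 * (se_cc / se_mi - 1.0)
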