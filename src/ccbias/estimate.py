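"""Complete-case logistic estimation and multiple imputation by chained
equations with Rubin's-rules pooling.

The analysis model throughout is the logistic regression of the binary outcome
on the binary exposure; the imputation model for the outcome additionally uses
the misclassified proxy as an auxiliary predictor.  Imputation is *proper*:
each imputed dataset uses imputation-model parameters drawn from the
approximate posterior (asymptotic normal around the MLE with the
inverse-observed-information covariance; a bootstrap-refit draw is available
as an alternative).  Pooling follows Rubin's rules with the small-sample
degrees of freedom and the df-adjusted fraction of missing information.

The logistic fitter is a Newton–Raphson (IRLS) iteration written directly on
NumPy: the simulation study performs hundreds of thousands of small fits
inside chained-equations burn-in loops, where per-fit overhead dominates
run time.  It reports the observed-information Wald SE, converges on a score
sup-norm below 1e-8, and flags separation instead of silently returning
divergent coefficients.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit


# ---------------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Exposure log OR from one logistic fit.

    ``params``/``cov`` hold the full coefficient vector and its
    observed-information covariance (needed for proper imputation draws);
    ``estimate``/``se`` are the exposure entry of each.
    """

    estimate: float
    se: float
    n_used: int
    converged: bool
    params: np.ndarray | None = None
    cov: np.ndarray | None = None
    message: str = ""


_SCORE_TOL = 1e-8
_MAX_ITER = 40
_MAX_ABS_COEF = 35.0  # beyond this the likelihood is flat: treat as separation


def _newton_logistic(y: np.ndarray, X: np.ndarray, beta0: np.ndarray | None = None,
                     trials: np.ndarray | None = None):
    """Newton–Raphson MLE for (optionally grouped) logistic regression.

    With ``trials`` given, row i of X is a covariate pattern observed
    ``trials[i]`` times with ``y[i]`` successes (binomial likelihood — the
    same MLE and observed information as the ungrouped Bernoulli fit).
    Returns (beta, cov, converged, message); cov is the inverse observed
    information at the optimum.  ``beta0`` warm-starts the iteration (used by
    the chained-equations burn-in, where successive fits barely move).
    Step-halving on the log-likelihood kicks in only for large proposed steps,
    keeping the common well-conditioned fit cheap.
    """
    n = np.ones(X.shape[0]) if trials is None else trials
    beta = np.zeros(X.shape[1]) if beta0 is None else beta0.copy()
    for _ in range(_MAX_ITER):
        eta = X @ beta
        prob = expit(eta)
        score = X.T @ (y - n * prob)
        w = np.clip(n * prob * (1.0 - prob), 1e-12, None)
        H = (X * w[:, None]).T @ X
        if np.max(np.abs(score)) < _SCORE_TOL:
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return beta, None, False, "singular information at optimum"
            return beta, cov, True, ""
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return beta, None, False, "singular information"
        if np.max(np.abs(step)) > 2.0:
            # guard against overshoot: halve until the log-likelihood improves
            ll = float(y @ eta - n @ np.logaddexp(0.0, eta))
            for _ in range(25):
                eta_c = X @ (beta + step)
                if float(y @ eta_c - n @ np.logaddexp(0.0, eta_c)) >= ll - 1e-12:
                    break
                step *= 0.5
        beta = beta + step
        if np.max(np.abs(beta)) > _MAX_ABS_COEF:
            return beta, None, False, "separation (diverging coefficients)"
    return beta, None, False, "no convergence after max iterations"


def _fit_binary_design(y: np.ndarray, X: np.ndarray,
                       beta0: np.ndarray | None = None):
    """Fit a logistic model, collapsing to covariate-pattern counts first when
    every design entry is 0/1 (the study's designs are all binary, so fits
    reduce to a handful of binomial cells regardless of cohort size)."""
    if X.shape[1] <= 20 and bool(((X == 0.0) | (X == 1.0)).all()):
        p = X.shape[1]
        code = (X.astype(np.int64) @ (1 << np.arange(p))).ravel()
        counts = np.bincount(code, minlength=1 << p)
        succ = np.bincount(code, weights=y, minlength=1 << p)
        keep = counts > 0
        X_cells = ((np.nonzero(keep)[0][:, None] >> np.arange(p)) & 1).astype(float)
        return _newton_logistic(succ[keep], X_cells, beta0=beta0,
                                trials=counts[keep].astype(float))
    return _newton_logistic(y, X, beta0=beta0)


def fit_logistic(outcome, design, coef_index: int = 1) -> FitResult:
    """ML logistic fit; ``coef_index`` selects the reported coefficient
    (default: the first column after the intercept, i.e. the exposure)."""
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design must be n x p aligned with the outcome")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size < 2:
        raise ValueError("outcome must contain both 0s and 1s")
    if np.linalg.matrix_rank(X.T @ X) < X.shape[1]:  # p x p Gram: cheap rank check
        raise ValueError("design matrix is rank deficient")
    beta, cov, converged, msg = _fit_binary_design(y, X)
    se = float(np.sqrt(cov[coef_index, coef_index])) if cov is not None else float("nan")
    return FitResult(
        estimate=float(beta[coef_index]),
        se=se,
        n_used=int(y.shape[0]),
        converged=converged,
        params=beta,
        cov=cov,
        message=msg,
    )


def complete_case_estimate(cohort: pd.DataFrame) -> FitResult:
    """Logistic fit of outcome on exposure restricted to observed records."""
    cc = cohort[cohort["r"] == 1]
    y = cc["d"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(cc)), cc["x"].to_numpy(dtype=float)])
    return fit_logistic(y, X)


# ---------------------------------------------------------------------------
# proper imputation
# ---------------------------------------------------------------------------

def _impute_binary(target: np.ndarray, cols: tuple[np.ndarray, ...],
                   missing: np.ndarray, rng: np.random.Generator, draw: str,
                   beta0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Proper single imputation of a binary vector given binary predictors.

    Fits the logistic of target on the predictor columns over the observed
    rows (collapsed to covariate-pattern cells, so the fit cost is independent
    of cohort size), draws a parameter vector from its approximate posterior,
    and fills the missing rows with Bernoulli draws at the drawn-parameter
    probabilities.  Returns (completed vector, MLE) so burn-in cycles can
    warm-start the next fit.
    """
    obs = ~missing
    y_obs = target[obs]
    if y_obs.min() == y_obs.max():
        raise RuntimeError("imputation model degenerate: observed target is constant")
    p = len(cols)
    code = np.zeros(target.shape[0], dtype=np.int64)
    for j, col in enumerate(cols):
        code += (col > 0.5).astype(np.int64) << j
    ncell = 1 << p
    counts = np.bincount(code[obs], minlength=ncell).astype(float)
    succ = np.bincount(code[obs], weights=y_obs, minlength=ncell)
    keep = counts > 0
    X_cells = np.column_stack([
        np.ones(int(keep.sum())),
        ((np.nonzero(keep)[0][:, None] >> np.arange(p)) & 1).astype(float),
    ])
    mle, cov, converged, msg = _newton_logistic(succ[keep], X_cells, beta0=beta0,
                                                trials=counts[keep])
    if not converged:
        raise RuntimeError(f"imputation model did not converge: {msg}")
    if draw == "normal":
        beta = mle + np.linalg.cholesky(cov) @ rng.standard_normal(len(mle))
    elif draw == "bootstrap":
        # row-level bootstrap via a multinomial over (cell, outcome) counts
        joint = np.concatenate([succ[keep], counts[keep] - succ[keep]])
        resamp = rng.multinomial(int(counts.sum()), joint / joint.sum())
        k = int(keep.sum())
        beta, _, conv, msg = _newton_logistic(
            resamp[:k].astype(float), X_cells, beta0=mle,
            trials=(resamp[:k] + resamp[k:]).astype(float))
        if not conv:
            raise RuntimeError(f"bootstrap refit failed: {msg}")
    else:
        raise ValueError(f"unknown draw method {draw!r}")
    # per-cell imputation probabilities, looked up by the row's pattern code
    X_all = np.column_stack([
        np.ones(ncell), ((np.arange(ncell)[:, None] >> np.arange(p)) & 1).astype(float)])
    p_cell = expit(X_all @ beta)
    out = target.copy()
    out[missing] = (rng.random(int(missing.sum())) < p_cell[code[missing]]).astype(float)
    return out, mle


def impute_once(cohort: pd.DataFrame, rng: np.random.Generator,
                draw: str = "normal") -> np.ndarray:
    """One proper imputation of the binary outcome from (exposure, proxy).

    Requires the proxy to be fully observed; partially observed proxies go
    through :func:`chained_imputation`.
    """
    d = cohort["d"].to_numpy(dtype=float)
    a = cohort["a"].to_numpy(dtype=float)
    x = cohort["x"].to_numpy(dtype=float)
    if np.isnan(a).any():
        raise ValueError("proxy has missing values: use chained_imputation")
    missing = np.isnan(d)
    if not missing.any():
        return d.copy()
    return _impute_binary(d, (x, a), missing, rng, draw)[0]


def chained_imputation(cohort: pd.DataFrame, rng: np.random.Generator,
                       burn_in: int = 20, draw: str = "normal"
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Chained-equations imputation of (outcome, proxy).

    Alternates proper imputation of proxy | (exposure, outcome) and
    outcome | (exposure, proxy) for ``burn_in`` cycles and returns the final
    completed pair.  Degenerate patterns short-circuit: a fully observed proxy
    reduces to a single outcome imputation, a fully observed outcome to a
    single proxy imputation.
    """
    d = cohort["d"].to_numpy(dtype=float)
    a = cohort["a"].to_numpy(dtype=float)
    x = cohort["x"].to_numpy(dtype=float)
    d_mis, a_mis = np.isnan(d), np.isnan(a)
    if not a_mis.any():
        return impute_once(cohort, rng, draw=draw), a.copy()
    if not d_mis.any():
        return d.copy(), _impute_binary(a, (x, d), a_mis, rng, draw)[0]
    # initialise missing cells from the observed marginals
    d_fill, a_fill = d.copy(), a.copy()
    d_fill[d_mis] = rng.choice(d[~d_mis], size=d_mis.sum())
    a_fill[a_mis] = rng.choice(a[~a_mis], size=a_mis.sum())
    beta_a = beta_d = None
    for _ in range(max(1, burn_in)):
        a_fill, beta_a = _impute_binary(a, (x, d_fill), a_mis, rng, draw, beta0=beta_a)
        d_fill, beta_d = _impute_binary(d, (x, a_fill), d_mis, rng, draw, beta0=beta_d)
    return d_fill, a_fill


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PooledResult:
    """Rubin's-rules pooled estimate with fraction of missing information."""

    m: int
    qbar: float
    w: float
    b: float
    t: float
    se: float
    df: float
    fmi: float
    fmi_simple: float
    n_failed: int = 0


def pool(estimates, variances) -> PooledResult:
    """Pool per-imputation estimates and squared SEs by Rubin's rules.

    t = w + (1 + 1/m) b; df = (m-1)(1 + w/((1+1/m) b))^2;
    fmi = (r + 2/(df+3))/(r + 1) with r = (1+1/m) b / w (the df-adjusted
    convention); fmi_simple = (b + b/m)/t is also reported.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m < 2:
        raise ValueError("pooling requires at least 2 imputations")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b > 0.0:
        r = (1.0 + 1.0 / m) * b / w
        df = (m - 1) * (1.0 + 1.0 / r) ** 2
        fmi = (r + 2.0 / (df + 3.0)) / (r + 1.0)
    else:
        df = float("inf")
        fmi = 0.0
    return PooledResult(
        m=m, qbar=qbar, w=w, b=b, t=t, se=math.sqrt(t), df=df, fmi=fmi,
        fmi_simple=(b + b / m) / t if t > 0 else 0.0,
    )


def mi_estimate(cohort: pd.DataFrame, m: int, rng: np.random.Generator,
                burn_in: int = 20, draw: str = "normal") -> PooledResult:
    """Multiple imputation of the exposure log OR: m completed datasets, each
    analysed with the exposure-only logistic model, pooled by Rubin's rules."""
    if m < 2:
        raise ValueError("m must be at least 2")
    x = cohort["x"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(cohort)), x])
    estimates, variances, failed = [], [], 0
    for _ in range(m):
        d_comp, _ = chained_imputation(cohort, rng, burn_in=burn_in, draw=draw)
        fit = fit_logistic(d_comp, X)
        if fit.converged:
            estimates.append(fit.estimate)
            variances.append(fit.se ** 2)
        else:
            failed += 1
    if len(estimates) < 2:
        raise RuntimeError("fewer than 2 converged per-imputation fits")
    pooled = pool(estimates, variances)
    return dataclasses.replace(pooled, n_failed=failed)
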