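"""Propensity-score estimation and inverse-probability-of-treatment weighting.

The propensity score e_i = Pr(anti-pseudomonal | covariates) is fit by
maximum-likelihood logistic regression (Newton-Raphson with step-halving).
Average-treatment-effect weights are w = 1/e for the exposed and 1/(1-e) for
the unexposed, so each arm is re-weighted to resemble the covariate
distribution of the whole cohort. Balance is reported as standardized mean
differences before and after weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    CollinearityError,
    ContractViolation,
    DegenerateScoreError,
    SeparationError,
)

__all__ = ["PropensityFit", "fit_logistic", "ate_weights", "balance_smd", "fit_iptw"]


@dataclass
class PropensityFit:
    coefficients: pd.Series          # intercept + per-covariate log-odds
    fitted_score: np.ndarray         # e_i in (0,1)
    converged: bool
    n_iterations: int
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    weights: Optional[np.ndarray] = None
    smd_table: Optional[pd.DataFrame] = None


def _design(rows: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(rows))] +
                        [rows[c].to_numpy(dtype=float) for c in covariates])
    if np.isnan(X).any():
        raise ContractViolation("design matrix contains missing values; "
                                "filter to complete cases first")
    return X

_MAX_ABS_BETA = 50.0  # |log-odds| beyond this on a standardized column => separation


def fit_logistic(rows: pd.DataFrame, covariates: list[str],
                 exposure_col: str = "exposure",
                 tol: float = 1e-8, max_iter: int = 100) -> PropensityFit:
    """Maximize the binomial log-likelihood by Newton-Raphson.

    Convergence when the max absolute score (gradient) falls below ``tol``.
    Raises :class:`CollinearityError` naming a redundant covariate and
    :class:`SeparationError` on perfect separation.
    """
    y = rows[exposure_col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ContractViolation("need at least one exposed and one unexposed row")
    X = _design(rows, covariates)
    names = ["intercept"] + list(covariates)

    # rank check with a named culprit
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise CollinearityError(
                    f"covariate {names[j]!r} is collinear with the rest of the design")
        raise CollinearityError("design matrix is rank deficient")

    beta, fitted, converged, it, ll, trace = _newton_logistic(X, y, tol, max_iter)
    return PropensityFit(
        coefficients=pd.Series(beta, index=names),
        fitted_score=fitted,
        converged=converged,
        n_iterations=it,
        loglik=ll,
        loglik_trace=trace,
    )


def _newton_logistic(X: np.ndarray, y: np.ndarray,
                     tol: float = 1e-8, max_iter: int = 100):
    """Newton-Raphson MLE on a prebuilt design matrix (fast path for the
    bias-analysis inner loop)."""
    scale = np.abs(X).max(axis=0)
    beta = np.zeros(X.shape[1])
    trace: list[float] = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        if np.abs(grad).max() < tol:
            trace.append(ll)
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information; likely perfect separation") from exc
        # step-halving keeps the log-likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = float(np.sum(y * (X @ cand) - np.logaddexp(0.0, X @ cand)))
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        trace.append(ll)
        if np.abs(beta * scale).max() > _MAX_ABS_BETA and ll - ll_old < 1e-9:
            raise SeparationError("perfect separation: coefficients diverging")
        ll_old = ll
    if np.abs(beta * scale).max() > _MAX_ABS_BETA:
        raise SeparationError("perfect separation: coefficients diverging")
    eta = X @ beta
    fitted = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if ll > -1e-5:
        # a (near-)zero maximized log-likelihood means the model classifies
        # perfectly: the score vanishes only because probabilities saturated
        raise SeparationError("perfect separation: fitted probabilities saturated")
    return beta, fitted, converged, it, ll, trace


def ate_weights(fit: PropensityFit, rows: pd.DataFrame,
                exposure_col: str = "exposure",
                truncate_percentiles: tuple[float, float] | None = None) -> np.ndarray:
    """ATE inverse-probability weights: 1/e if exposed, 1/(1-e) if not.

    No truncation by default; ``truncate_percentiles=(lo, hi)`` clips the
    weights at those percentiles for sensitivity use.
    """
    e = np.asarray(fit.fitted_score, dtype=float)
    eps = 1e-12
    if np.any(e <= eps) or np.any(e >= 1 - eps):
        raise DegenerateScoreError("fitted propensity score numerically 0 or 1")
    exposed = rows[exposure_col].to_numpy(dtype=float) == 1
    w = np.where(exposed, 1.0 / e, 1.0 / (1.0 - e))
    if truncate_percentiles is not None:
        lo, hi = np.percentile(w, truncate_percentiles)
        w = np.clip(w, lo, hi)
    return w


def balance_smd(rows: pd.DataFrame, covariates: list[str],
                weights: np.ndarray | None = None,
                exposure_col: str = "exposure") -> pd.DataFrame:
    """Standardized mean differences before/after weighting.

    SMD = (mean_exposed - mean_unexposed) / pooled SD, with the pooled SD
    always taken from the *unweighted* arms (proportion-based for binaries,
    which the variance formula covers automatically). Zero pooled SD yields
    SMD 0 with a warning.
    """
    if weights is None:
        weights = np.ones(len(rows))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ContractViolation("weights must be positive")
    exposed = rows[exposure_col].to_numpy(dtype=float) == 1
    out = []
    for cov in covariates:
        x = rows[cov].to_numpy(dtype=float)
        sd_pool = np.sqrt((np.var(x[exposed], ddof=1) + np.var(x[~exposed], ddof=1)) / 2.0)

        def smd(w):
            m1 = np.average(x[exposed], weights=w[exposed])
            m0 = np.average(x[~exposed], weights=w[~exposed])
            if sd_pool == 0:
                return 0.0
            return (m1 - m0) / sd_pool

        if sd_pool == 0:
            warnings.warn(f"zero pooled SD for {cov!r}; SMD reported as 0")
        out.append({"covariate": cov,
                    "smd_unweighted": smd(np.ones_like(weights)),
                    "smd_weighted": smd(weights)})
    return pd.DataFrame(out).set_index("covariate")


def fit_iptw(rows: pd.DataFrame, covariates: list[str],
             exposure_col: str = "exposure", **kwargs) -> PropensityFit:
    """Convenience: fit the propensity model, attach ATE weights and the
    balance table."""
    fit = fit_logistic(rows, covariates, exposure_col=exposure_col, **kwargs)
    fit.weights = ate_weights(fit, rows, exposure_col=exposure_col)
    fit.smd_table = balance_smd(rows, covariates, fit.weights, exposure_col=exposure_col)
    return fit
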