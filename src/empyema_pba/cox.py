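"""Cause-specific hazard estimation under competing risks.

The exposure effect on each cause (thoracic surgery; all-cause death) is
estimated from the case-weighted Cox partial likelihood with Efron tie
handling -- ties are ubiquitous on integer-day data -- maximized by Newton
iteration. Confounding is carried entirely by the IPTW weights, so exposure is
the sole model covariate in the study analysis (the fitter itself accepts any
design). Variance uses the subject-level sandwich estimator with the weights
treated as fixed known quantities; propensity-estimation uncertainty is not
propagated, matching the robust-standard-error convention of weighted Cox
analyses (a nonparametric bootstrap is available for users who want it).

Unadjusted cumulative incidence functions use the Aalen-Johansen estimator on
the first-event decomposition (same-day surgery + death counts as surgery
first), which conserves mass exactly: CIF_surgery + CIF_death + event-free
probability = 1 at every time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ContractViolation,
    DegenerateFitError,
    DivergenceError,
    NoEventsError,
)

__all__ = [
    "CauseSpecificCoxFit",
    "CIFEstimate",
    "fit_weighted_cox",
    "robust_sandwich_se",
    "cumulative_incidence",
    "weighted_survival_curves",
    "bootstrap_se",
]


@dataclass
class CauseSpecificCoxFit:
    cause: str
    log_hr: float
    hr: float
    robust_se: float
    model_se: float
    ci95: tuple[float, float]      # on the HR scale
    p_value: float
    n_used: int
    n_events: int
    converged: bool
    n_iterations: int
    low_information: bool
    coefficients: np.ndarray = field(repr=False, default=None)
    robust_se_all: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "cause": self.cause, "hr": self.hr, "log_hr": self.log_hr,
            "robust_se": self.robust_se,
            "ci95_low": self.ci95[0], "ci95_high": self.ci95[1],
            "p_value": self.p_value, "n": self.n_used, "events": self.n_events,
        }


def _prepare(time, event, X, weights):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ContractViolation("weights must be positive")
    if np.isnan(X).any() or np.isnan(t).any():
        raise ContractViolation("missing values in Cox input; filter to complete cases")
    order = np.argsort(t, kind="stable")
    return t[order], e[order], X[order], w[order]


def _event_blocks(t, e):
    """Unique event times with (start index in sorted t, member indices of the
    tied event set)."""
    ev_times = np.unique(t[e == 1])
    blocks = []
    for tau in ev_times:
        start = np.searchsorted(t, tau, side="left")
        members = np.where((t == tau) & (e == 1))[0]
        blocks.append((tau, start, members))
    return blocks


def _efron_loglik(beta, t, e, X, w, blocks, need_derivs=True):
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    wr = w * np.exp(eta)
    wrx = wr[:, None] * X
    # suffix sums give risk-set aggregates (t sorted ascending)
    S0_suf = np.concatenate([np.cumsum(wr[::-1])[::-1], [0.0]])
    S1_suf = np.vstack([np.cumsum(wrx[::-1], axis=0)[::-1], np.zeros(X.shape[1])])
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for tau, start, members in blocks:
        d = len(members)
        wD = w[members]
        wbar = wD.sum() / d
        S0R = S0_suf[start]
        S1R = S1_suf[start]
        S0D = wr[members].sum()
        S1D = wrx[members].sum(axis=0)
        if need_derivs:
            xm = X[members]
            S2R = np.einsum("i,ij,ik->jk", wr[start:], X[start:], X[start:])
            S2D = np.einsum("i,ij,ik->jk", wr[members], xm, xm)
        ll += float(np.dot(wD, eta[members]))
        for l in range(d):
            c = l / d
            s0 = S0R - c * S0D
            ll -= wbar * np.log(s0)
            if need_derivs:
                s1 = S1R - c * S1D
                s2 = S2R - c * S2D
                xbar = s1 / s0
                grad_term = xbar
                info += wbar * (s2 / s0 - np.outer(xbar, xbar))
                grad -= wbar * grad_term
        if need_derivs:
            grad += xm.T @ wD
    return (ll, grad, info) if need_derivs else ll


def _suffix(a):
    return np.concatenate([np.cumsum(a[::-1])[::-1], [0.0]])


def _efron_loglik_1d(beta, t, e, x, w, need_derivs=True):
    """Vectorized Efron log-likelihood for a single covariate (the study
    model: exposure only). Same quantities as :func:`_efron_loglik`."""
    ev = np.flatnonzero(e == 1)
    t_ev = t[ev]
    bounds = np.flatnonzero(np.r_[True, np.diff(t_ev) != 0])
    taus = t_ev[bounds]
    d = np.diff(np.r_[bounds, len(ev)]).astype(float)
    starts = np.searchsorted(t, taus, side="left")

    eta = np.clip(x * beta, -500, 500)
    wr = w * np.exp(eta)
    wrx = wr * x
    S0R = _suffix(wr)[starts]
    S1R = _suffix(wrx)[starts]
    S0D = np.add.reduceat(wr[ev], bounds)
    S1D = np.add.reduceat(wrx[ev], bounds)
    wD = np.add.reduceat(w[ev], bounds)
    wbar = wD / d

    k_idx = np.repeat(np.arange(len(d)), d.astype(int))
    l = np.arange(len(ev)) - np.repeat(np.cumsum(d) - d, d.astype(int))
    c = l / d[k_idx]
    s0 = S0R[k_idx] - c * S0D[k_idx]
    wb = wbar[k_idx]
    ll = float(np.dot(w[ev], eta[ev]) - np.dot(wb, np.log(s0)))
    if not need_derivs:
        return ll
    S2R = _suffix(wrx * x)[starts]
    S2D = np.add.reduceat((wrx * x)[ev], bounds)
    s1 = S1R[k_idx] - c * S1D[k_idx]
    s2 = S2R[k_idx] - c * S2D[k_idx]
    xb = s1 / s0
    grad = float(np.dot(w[ev], x[ev]) - np.dot(wb, xb))
    info = float(np.dot(wb, s2 / s0 - xb * xb))
    return ll, np.array([grad]), np.array([[info]])


def _newton(t, e, X, w, tol, max_iter):
    if not np.any(e == 1):
        raise NoEventsError("no events of the requested cause")
    if X.shape[1] == 1:
        x1 = X[:, 0]

        def loglik(beta, need_derivs=True):
            return _efron_loglik_1d(float(beta[0]), t, e, x1, w, need_derivs)
    else:
        blocks_ = _event_blocks(t, e)

        def loglik(beta, need_derivs=True):
            return _efron_loglik(beta, t, e, X, w, blocks_, need_derivs)
    p = X.shape[1]
    beta = np.zeros(p)
    scale = np.abs(X).max(axis=0)
    scale[scale == 0] = 1.0
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        ll, grad, info = loglik(beta)
        if np.abs(grad).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError("singular information matrix") from exc
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            if loglik(cand, need_derivs=False) >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.abs(beta * scale).max() > 200.0:
            raise DivergenceError(
                "monotone partial likelihood (coefficients diverging); "
                "consider a Firth-style penalized fallback")
    if not converged:
        raise DivergenceError(f"Cox Newton iteration did not converge in {max_iter} steps")
    _, _, info = loglik(beta)
    return beta, info, None, n_iter


def robust_sandwich_se(time, event, X, weights, beta):
    """Subject-level sandwich variance at ``beta``.

    V = I^{-1} (sum_i U_i U_i^T) I^{-1} with U_i the weighted per-subject
    score residual; weights are treated as fixed. Doubling all weights leaves
    the result unchanged. Returns ``(se, V)``.
    """
    t, e, X, w = _prepare(time, event, X, weights)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    blocks = _event_blocks(t, e)
    _, _, info = _efron_loglik(beta, t, e, X, w, blocks)
    eta = np.clip(X @ beta, -500, 500)
    r = np.exp(eta)
    wr = w * r
    S0_suf = np.concatenate([np.cumsum(wr[::-1])[::-1], [0.0]])
    S1_suf = np.vstack([np.cumsum((wr[:, None] * X)[::-1], axis=0)[::-1],
                        np.zeros(X.shape[1])])
    n, p = X.shape
    # per-event-time aggregates
    taus = np.array([b[0] for b in blocks])
    dw = np.array([w[b[2]].sum() for b in blocks])              # weighted deaths
    S0 = np.array([S0_suf[b[1]] for b in blocks])
    xbar = np.vstack([S1_suf[b[1]] / S0_suf[b[1]] for b in blocks])
    # cumulative (over event times) hazard-increment sums
    A = np.cumsum(dw / S0)                                       # scalar per k
    B = np.cumsum((dw / S0)[:, None] * xbar, axis=0)             # p-vector per k
    idx = np.searchsorted(taus, t, side="right") - 1             # last event time <= t_i
    L = np.zeros((n, p))
    has = idx >= 0
    L[has] -= r[has, None] * (X[has] * A[idx[has], None] - B[idx[has]])
    # event subjects: own-time deviation
    ev = e == 1
    own = np.searchsorted(taus, t[ev])
    L[ev] += X[ev] - xbar[own]
    U = w[:, None] * L
    Bmat = U.T @ U
    try:
        inv_info = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("singular information matrix") from exc
    V = inv_info @ Bmat @ inv_info
    return np.sqrt(np.diag(V)), V


def fit_weighted_cox(rows: pd.DataFrame, weights=None, cause: str = "death",
                     covariate_cols: Sequence[str] = ("exposure",),
                     tol: float = 1e-8, max_iter: int = 100) -> CauseSpecificCoxFit:
    """Cause-specific weighted Cox fit; exposure is the sole covariate in the
    study analysis.

    ``rows`` must contain ``time_<cause>`` / ``event_<cause>`` columns.
    Raises :class:`NoEventsError` with zero events of the cause and
    :class:`DivergenceError` on a monotone likelihood.
    """
    time = rows[f"time_{cause}"].to_numpy(dtype=float)
    event = rows[f"event_{cause}"].to_numpy(dtype=int)
    X = rows[list(covariate_cols)].to_numpy(dtype=float)
    t, e, Xs, w = _prepare(time, event, X, weights)
    beta, info, blocks, n_iter = _newton(t, e, Xs, w, tol, max_iter)
    try:
        model_se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("singular information matrix") from exc
    rse, _ = robust_sandwich_se(t, e, Xs, w, beta)
    n_events = int(e.sum())
    b0, se0 = float(beta[0]), float(rse[0])
    z = b0 / se0 if se0 > 0 else np.inf
    return CauseSpecificCoxFit(
        cause=cause,
        log_hr=b0,
        hr=float(np.exp(b0)),
        robust_se=se0,
        model_se=float(model_se[0]),
        ci95=(float(np.exp(b0 - 1.959963984540054 * se0)),
              float(np.exp(b0 + 1.959963984540054 * se0))),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        n_used=len(t),
        n_events=n_events,
        converged=True,
        n_iterations=n_iter,
        low_information=n_events < 2,
        coefficients=beta,
        robust_se_all=rse,
    )


def bootstrap_se(rows: pd.DataFrame, cause: str, covariates_for_ps: list[str] | None,
                 n_boot: int, seed: int, weights=None) -> float:
    """Nonparametric bootstrap SE of the log-HR (resampling subjects).

    If ``covariates_for_ps`` is given, the propensity model and weights are
    re-estimated inside each resample (propagating weight-estimation
    uncertainty); otherwise the supplied weights are resampled alongside rows.
    """
    from .propensity import fit_iptw

    rng = np.random.default_rng(seed)
    n = len(rows)
    if weights is None:
        weights = np.ones(n)
    est = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = rows.iloc[idx].reset_index(drop=True)
        # the log-HR is unidentified when an arm has no events of the cause
        events = sample.groupby("exposure")[f"event_{cause}"].sum()
        if len(events) < 2 or (events == 0).any():
            continue
        try:
            if covariates_for_ps is not None:
                f = fit_iptw(sample, covariates_for_ps)
                wb = f.weights
            else:
                wb = np.asarray(weights)[idx]
            est.append(fit_weighted_cox(sample, wb, cause).log_hr)
        except Exception:
            continue
    return float(np.std(est, ddof=1))


# ---------------------------------------------------------------------------
# cumulative incidence
# ---------------------------------------------------------------------------

@dataclass
class CIFEstimate:
    group: Optional[str]
    time_grid: np.ndarray
    cif_surgery: np.ndarray
    cif_death: np.ndarray
    event_free: np.ndarray
    se_surgery: np.ndarray
    se_death: np.ndarray
    band_surgery: tuple[np.ndarray, np.ndarray]
    band_death: tuple[np.ndarray, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time_grid,
            "cif_surgery": self.cif_surgery,
            "cif_surgery_low": self.band_surgery[0],
            "cif_surgery_high": self.band_surgery[1],
            "cif_death": self.cif_death,
            "cif_death_low": self.band_death[0],
            "cif_death_high": self.band_death[1],
            "event_free": self.event_free,
            "group": self.group,
        })


def _cif_variance(taus, Y, d_all, d_cause, S_prev, cif):
    """Pointwise variance of the Aalen-Johansen CIF (delta-method estimator)."""
    k = len(taus)
    var = np.zeros(k)
    for j in range(k):
        F_t = cif[j]
        t1 = t2 = t3 = 0.0
        for i in range(j + 1):
            if Y[i] <= 0:
                continue
            diff = F_t - cif[i]
            if Y[i] > d_all[i]:
                t1 += diff ** 2 * d_all[i] / (Y[i] * (Y[i] - d_all[i]))
            t2 += S_prev[i] ** 2 * ((Y[i] - d_cause[i]) / Y[i]) * d_cause[i] / Y[i] ** 2
            t3 += diff * S_prev[i] * d_cause[i] / Y[i] ** 2
        var[j] = t1 + t2 - 2.0 * t3
    return np.maximum(var, 0.0)


def _loglog_band(cif, se, z=1.959963984540054):
    low = np.zeros_like(cif)
    high = np.zeros_like(cif)
    pos = (cif > 0) & (cif < 1)
    theta = np.zeros_like(cif)
    theta[pos] = z * se[pos] / np.abs(cif[pos] * np.log(cif[pos]))
    low[pos] = cif[pos] ** np.exp(theta[pos])
    high[pos] = cif[pos] ** np.exp(-theta[pos])
    high[~pos] = cif[~pos]
    return low, high


def cumulative_incidence(rows: pd.DataFrame, group: Optional[str] = None,
                         exposure_col: str = "exposure_label") -> CIFEstimate:
    """Aalen-Johansen cumulative incidence of surgery and death (unadjusted).

    ``group`` filters to one exposure arm ('anti_pseudomonal' /
    'non_anti_pseudomonal'); ``None`` pools the cohort. At each event time the
    cause-specific increment uses the overall event-free survival just before
    t. Empty input yields an empty grid. Pointwise 95% bands use the
    log(-log) transform.
    """
    df = rows if group is None else rows[rows[exposure_col] == group]
    empty = np.array([])
    if len(df) == 0:
        return CIFEstimate(group, empty, empty, empty, empty, empty, empty,
                           (empty, empty), (empty, empty))
    # first-event decomposition: time_surgery is min(surgery, death, censor)
    T = df["time_surgery"].to_numpy(dtype=float)
    e_s = df["event_surgery"].to_numpy(dtype=int)
    e_d = df["event_death"].to_numpy(dtype=int)
    t_d = df["time_death"].to_numpy(dtype=float)
    cause = np.where(e_s == 1, 1, np.where((e_d == 1) & (t_d == T), 2, 0))

    taus = np.unique(T[cause > 0])
    if len(taus) == 0:
        z = np.zeros(1)
        return CIFEstimate(group, z, z.copy(), z.copy(), np.ones(1), z.copy(),
                           z.copy(), (z.copy(), z.copy()), (z.copy(), z.copy()))
    k = len(taus)
    Y = np.array([(T >= tau).sum() for tau in taus], dtype=float)
    d1 = np.array([((T == tau) & (cause == 1)).sum() for tau in taus], dtype=float)
    d2 = np.array([((T == tau) & (cause == 2)).sum() for tau in taus], dtype=float)
    d_all = d1 + d2
    S = 1.0
    S_prev = np.zeros(k)
    cif1 = np.zeros(k)
    cif2 = np.zeros(k)
    c1 = c2 = 0.0
    for j in range(k):
        S_prev[j] = S
        c1 += S * d1[j] / Y[j]
        c2 += S * d2[j] / Y[j]
        cif1[j], cif2[j] = c1, c2
        S = S * (1.0 - d_all[j] / Y[j])
    event_free = 1.0 - cif1 - cif2
    se1 = np.sqrt(_cif_variance(taus, Y, d_all, d1, S_prev, cif1))
    se2 = np.sqrt(_cif_variance(taus, Y, d_all, d2, S_prev, cif2))
    return CIFEstimate(group, taus, cif1, cif2, event_free, se1, se2,
                       _loglog_band(cif1, se1), _loglog_band(cif2, se2))


# ---------------------------------------------------------------------------
# weighted survival curves
# ---------------------------------------------------------------------------

def weighted_survival_curves(rows: pd.DataFrame, weights=None, cause: str = "death",
                             fit: Optional[CauseSpecificCoxFit] = None) -> pd.DataFrame:
    """Per-arm survival curves from the weighted Cox fit.

    The baseline (unexposed) survival is the product-integral of the weighted
    Breslow cumulative-hazard increments, so with a null effect and unit
    weights it reduces to the Kaplan-Meier curve; the exposed curve raises the
    baseline to exp(log_hr). Bands reflect the robust uncertainty of the
    log-HR only (the exposed-vs-baseline contrast), so the baseline arm
    carries the point estimate with a degenerate band.
    """
    if fit is None:
        fit = fit_weighted_cox(rows, weights, cause)
    time = rows[f"time_{cause}"].to_numpy(dtype=float)
    event = rows[f"event_{cause}"].to_numpy(dtype=int)
    x = rows["exposure"].to_numpy(dtype=float)
    t, e, X, w = _prepare(time, event, x, weights)
    beta = float(fit.log_hr)
    wr = w * np.exp(np.clip(X[:, 0] * beta, -500, 500))
    blocks = _event_blocks(t, e)
    taus = np.array([b[0] for b in blocks])
    S0_suf = np.concatenate([np.cumsum(wr[::-1])[::-1], [0.0]])
    dH0 = np.array([w[b[2]].sum() / S0_suf[b[1]] for b in blocks])

    def curve(b, g):
        return np.cumprod(np.clip(1.0 - np.exp(b * g) * dH0, 0.0, 1.0))

    z = 1.959963984540054
    frames = []
    for g, label in ((0, "non_anti_pseudomonal"), (1, "anti_pseudomonal")):
        est = curve(beta, g)
        lo = curve(beta + z * fit.robust_se, g)   # survival decreasing in beta
        hi = curve(beta - z * fit.robust_se, g)
        frames.append(pd.DataFrame({
            "time": taus, "estimate": est,
            "low": lo if g else est, "high": hi if g else est,
            "group": label}))
    return pd.concat(frames, ignore_index=True)
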