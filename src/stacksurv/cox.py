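"""Cox proportional-hazards machinery: Breslow partial likelihood, Newton
fitting with step-halving, Schoenfeld residuals and the Breslow baseline
hazard.

This module is the numerical core shared by the univariate screen, the
spike-and-slab selector, the stacking meta-fit and the proportional-hazards
check. Tie handling is Breslow throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoxData",
    "CoxFit",
    "cox_loglik",
    "fit_cox",
    "schoenfeld_residuals",
    "breslow_cumhazard",
]

#: |beta| above which the likelihood is treated as monotone (perfect separation)
_BETA_CAP = 15.0


class CoxData:
    """Pre-sorted survival data for repeated partial-likelihood evaluation.

    Samples are sorted by descending time so that the risk set at each event
    time is a prefix of the sorted arrays; tied times form contiguous groups.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.size == 0:
            raise ValueError("empty survival data")
        if event.sum() < 1:
            raise ValueError("Cox fit requires at least one event")
        order = np.argsort(-time, kind="mergesort")
        self.order = order
        self.time = time[order]
        self.event = event[order]
        self.n = time.size
        # inclusive end index of each tied-time group, descending time order
        ends = np.flatnonzero(np.diff(self.time) != 0)
        self.group_end = np.r_[ends, self.n - 1]
        self.n_events = int(event.sum())
        # per-group death counts; retain only groups with deaths (the only
        # ones contributing to the Breslow partial likelihood)
        starts = np.r_[0, self.group_end[:-1] + 1]
        cum_ev = np.r_[0, np.cumsum(self.event)]
        d = cum_ev[self.group_end + 1] - cum_ev[starts]
        keep = d > 0
        self.event_group_end = self.group_end[keep]
        self.event_group_d = d[keep].astype(float)
        self.death_idx = np.flatnonzero(self.event == 1)

    def sort(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X[self.order]


def cox_loglik(data: CoxData, Xs: np.ndarray, beta: np.ndarray,
               order: int = 2):
    """Breslow partial log-likelihood and derivatives at ``beta``.

    Parameters
    ----------
    data
        Pre-sorted :class:`CoxData`.
    Xs
        Covariates already sorted by ``data.sort`` (n x p).
    order
        0 -> loglik only; 1 -> + score; 2 -> + observed information.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = Xs @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    cw = np.cumsum(w)
    ends = data.event_group_end
    d = data.event_group_d
    S0 = cw[ends]
    ll = float(eta[data.death_idx].sum() - d @ (np.log(S0) + shift))
    if order == 0:
        return ll
    cXw = np.cumsum(Xs * w[:, None], axis=0)
    xbar = cXw[ends] / S0[:, None]  # groups x p
    score = Xs[data.death_idx].sum(axis=0) - d @ xbar
    if order == 1:
        return ll, score
    cXXw = np.cumsum(w[:, None, None] * Xs[:, :, None] * Xs[:, None, :], axis=0)
    info = np.einsum("g,gij->ij", d, cXXw[ends] / S0[:, None, None]) \
        - np.einsum("g,gi,gj->ij", d, xbar, xbar)
    return ll, score, info


@dataclass
class CoxFit:
    beta: np.ndarray
    loglik: float
    covariance: np.ndarray
    n_iter: int
    converged: bool
    monotone_likelihood: bool = False

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def fit_cox(covariates, outcome, penalty_weights=None, *, max_iter: int = 50,
            score_tol: float = 1e-8) -> CoxFit:
    """Maximize the Breslow Cox partial likelihood by Newton-Raphson.

    Step-halving enforces a non-decreasing (penalized) log-likelihood.
    ``penalty_weights`` adds an optional per-covariate ridge penalty
    ``-0.5 * w_j * beta_j**2``, used to stabilize degenerate columns.
    Convergence: max |score| < 1e-8 or 50 iterations. A coefficient
    escaping |beta| > 15 flags a monotone likelihood (perfect separation)
    and is capped with a warning.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    data = CoxData(outcome.time, outcome.event)
    if X.shape[0] != data.n:
        raise ValueError("covariate rows must match outcome length")
    Xs = data.sort(X)
    p = X.shape[1]
    pen = np.zeros(p) if penalty_weights is None else np.asarray(penalty_weights, float)
    if penalty_weights is None:
        const = Xs.std(axis=0) == 0
        if const.any():
            raise ValueError(
                f"constant covariate column(s) {np.flatnonzero(const).tolist()} "
                "cannot be fit unpenalized"
            )

    def penalized(ll, b):
        return ll - 0.5 * float(pen @ b**2)

    beta = np.zeros(p)
    ll, score, info = cox_loglik(data, Xs, beta)
    pll = penalized(ll, beta)
    converged = False
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        g = score - pen * beta
        H = info + np.diag(pen)
        if np.max(np.abs(g)) < score_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step-halving: never decrease the penalized log-likelihood
        for _ in range(30):
            cand = beta + step
            ll_c = cox_loglik(data, Xs, cand, order=0)
            if penalized(ll_c, cand) >= pll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(beta)) > _BETA_CAP:
            monotone = True
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            warnings.warn(
                "monotone partial likelihood (perfect separation); "
                f"coefficients capped at |beta|={_BETA_CAP}",
                stacklevel=2,
            )
            ll, score, info = cox_loglik(data, Xs, beta)
            pll = penalized(ll, beta)
            break
        ll, score, info = cox_loglik(data, Xs, beta)
        pll = penalized(ll, beta)
    else:
        warnings.warn("Cox Newton-Raphson did not converge", stacklevel=2)
    if converged is False and not monotone and np.max(np.abs(score - pen * beta)) < score_tol:
        converged = True
    H = info + np.diag(pen)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return CoxFit(beta=beta, loglik=ll, covariance=cov, n_iter=it,
                  converged=converged, monotone_likelihood=monotone)


def schoenfeld_residuals(covariates, outcome, beta):
    """Breslow Schoenfeld residuals, one row per event (death).

    Returns ``(event_times, residuals)`` with residuals shaped
    (n_events, p): x_i - xbar(t_i) for each death i, where xbar is the
    risk-set weighted covariate mean at the death's time.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    data = CoxData(outcome.time, outcome.event)
    Xs = data.sort(X)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = Xs @ beta
    w = np.exp(eta - eta.max())
    cw = np.cumsum(w)
    cXw = np.cumsum(Xs * w[:, None], axis=0)
    times, resid = [], []
    start = 0
    for end in data.group_end:
        sl = slice(start, end + 1)
        deaths = np.flatnonzero(data.event[sl] == 1) + start
        if deaths.size:
            xbar = cXw[end] / cw[end]
            for i in deaths:
                times.append(data.time[i])
                resid.append(Xs[i] - xbar)
        start = end + 1
    times = np.asarray(times)
    resid = np.asarray(resid)
    asc = np.argsort(times, kind="mergesort")
    return times[asc], resid[asc]


def breslow_cumhazard(eta, outcome):
    """Breslow estimator of the cumulative baseline hazard.

    Returns ``(times, H0)`` at the distinct event times; the survival
    function of a subject with linear predictor e is
    ``exp(-H0(t) * exp(e))`` (step-wise, right-continuous).
    """
    eta = np.asarray(eta, dtype=float)
    data = CoxData(outcome.time, outcome.event)
    es = eta[data.order]
    w = np.exp(es - es.max())
    cw = np.cumsum(w)
    times, increments = [], []
    start = 0
    for end in data.group_end:
        sl = slice(start, end + 1)
        d = int(data.event[sl].sum())
        if d > 0:
            times.append(data.time[end])
            increments.append(d / (cw[end] * np.exp(es.max())))
        start = end + 1
    times = np.asarray(times)[::-1]
    H0 = np.cumsum(np.asarray(increments)[::-1])
    return times, H0


def cumhazard_at(times, H0, t):
    """Evaluate a step cumulative hazard at (array of) times t."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(times, t, side="right") - 1
    out = np.where(idx >= 0, H0[np.clip(idx, 0, None)], 0.0)
    return out
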