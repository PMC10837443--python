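"""Discrimination, risk stratification and calibration for censored outcomes.

Implements cumulative/dynamic time-dependent ROC curves (nearest-neighbour
conditional-KM estimator by default, naive KM variant behind a flag),
maximally selected log-rank cut-points, Kaplan-Meier curves and log-rank
tests (via lifelines), grouped/population calibration tables, and the
Bonferroni threshold rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .types import SurvivalOutcome

__all__ = [
    "TdRocCurve", "CutpointResult", "KMCurve", "CalibrationTable",
    "BonferroniResult", "td_roc", "optimal_cutpoint", "km_curve",
    "logrank_test", "calibration", "bonferroni_adjust",
]


# ---------------------------------------------------------------------------
# time-dependent ROC


@dataclass
class TdRocCurve:
    eval_time: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    method: str = "nne"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < -1e-12) or np.any(np.diff(self.tpr) < -1e-12):
            raise ValueError("fpr/tpr must be non-decreasing")
        if not (abs(self.fpr[0]) < 1e-12 and abs(self.tpr[0]) < 1e-12
                and abs(self.fpr[-1] - 1) < 1e-9 and abs(self.tpr[-1] - 1) < 1e-9):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        trap = float(np.trapezoid(self.tpr, self.fpr))
        if abs(trap - self.auc) > 1e-9:
            raise ValueError("auc must equal the trapezoidal integral")


def _km_survival_at(time, event, t) -> float:
    """Product-limit survival at t (fast numpy path; hot inside the NNE
    ROC estimator)."""
    order = np.argsort(time, kind="mergesort")
    ts, es = time[order], np.asarray(event)[order]
    n = ts.size
    ut, first = np.unique(ts, return_index=True)
    at_risk = n - first
    d = np.add.reduceat(es, first)
    keep = (ut <= t) & (d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.prod(1.0 - d[keep] / at_risk[keep]))


def _nne_conditional_survival(marker, time, event, eval_time, span) -> np.ndarray:
    """S(eval_time | marker_i) by KM over a symmetric nearest-neighbour
    window in marker percentile space: neighbours j with
    |F(x_j) - F(x_i)| < span."""
    n = marker.size
    order = np.argsort(marker, kind="mergesort")
    F = np.empty(n)
    F[order] = (np.arange(n) + 1) / n
    S = np.empty(n)
    for i in range(n):
        nb = np.abs(F - F[i]) < span
        if nb.sum() < 2:
            nb = np.abs(F - F[i]) <= span
        S[i] = _km_survival_at(time[nb], event[nb], eval_time)
    return S


def td_roc(marker, outcome: SurvivalOutcome, eval_time: float, *,
           method: str = "nne", span: float = None) -> TdRocCurve:
    """Cumulative/dynamic time-dependent ROC at horizon ``eval_time``.

    Cases are subjects with an event by ``eval_time``; controls are subjects
    event-free beyond it. Censoring before the horizon is handled by the
    chosen bivariate-survival estimator:

    * ``method='nne'`` (default) — nearest-neighbour conditional KM over
      marker-sorted neighbourhoods with span 0.25 * n**-0.20; monotone by
      construction.
    * ``method='km'`` — naive subgroup-KM estimator; reduces exactly to the
      empirical ROC (Mann-Whitney AUC) when no observation is censored
      before the horizon. Minor non-monotonicities under censoring are
      repaired by running-maximum rearrangement.
    """
    marker = np.asarray(marker, dtype=float)
    time, event = outcome.time, outcome.event
    if marker.size != time.size:
        raise ValueError("marker and outcome must align")
    if eval_time <= 0 or eval_time >= time.max():
        raise ValueError("eval_time must lie within the follow-up range")
    cases = (time <= eval_time) & (event == 1)
    controls = time > eval_time
    if cases.sum() < 1 or controls.sum() < 1:
        raise ValueError("need at least one case and one control at eval_time")

    n = marker.size
    cuts = np.unique(marker)
    thresholds = np.r_[cuts, np.inf]  # P(X > c); +inf gives the (0,0) corner

    if method == "nne":
        if span is None:
            span = 0.25 * n ** (-0.20)
        S_i = _nne_conditional_survival(marker, time, event, eval_time, span)
        a = 1.0 - S_i  # soft case weight
        b = S_i        # soft control weight
        tpr = np.array([a[marker > c].sum() for c in thresholds]) / a.sum()
        fpr = np.array([b[marker > c].sum() for c in thresholds]) / b.sum()
    elif method == "km":
        S_t = _km_survival_at(time, event, eval_time)
        Sx = np.array([np.mean(marker > c) for c in thresholds])
        # joint S(c, t) = P(X > c) * KM(t | X > c)
        joint = np.array([
            (np.mean(marker > c)
             * _km_survival_at(time[marker > c], event[marker > c], eval_time))
            if (marker > c).any() else 0.0
            for c in thresholds
        ])
        with np.errstate(invalid="ignore"):
            tpr = (Sx - joint) / (1.0 - S_t)
            fpr = joint / S_t
        tpr = np.clip(tpr, 0.0, 1.0)
        fpr = np.clip(fpr, 0.0, 1.0)
    else:
        raise ValueError(f"unknown estimator {method!r}")

    # order from (0,0) to (1,1): descending threshold
    tpr, fpr = tpr[::-1], fpr[::-1]
    tpr[0] = fpr[0] = 0.0
    tpr[-1] = fpr[-1] = 1.0
    # monotone rearrangement (no-op for NNE and for uncensored KM)
    tpr = np.maximum.accumulate(tpr)
    fpr = np.maximum.accumulate(fpr)
    auc = float(np.trapezoid(tpr, fpr))
    return TdRocCurve(eval_time, fpr, tpr, auc, method)


# ---------------------------------------------------------------------------
# maximally selected log-rank cut-point


@dataclass
class CutpointResult:
    cutpoint: float
    max_standardized_statistic: float
    group_sizes: tuple  # (low, high)
    minprop: float
    scan: pd.DataFrame = None  # candidate midpoints with their statistics


def _two_group_logrank_z(high: np.ndarray, time: np.ndarray,
                         event: np.ndarray) -> float:
    """Standardized log-rank statistic z = (O - E)/sqrt(V) for the 'high'
    group, hypergeometric variance, ties pooled per distinct event time."""
    order = np.argsort(time, kind="mergesort")
    t, e, h = time[order], event[order], high[order].astype(float)
    n = t.size
    at_risk_total = n - np.arange(n)
    # per distinct time with events
    O = E = V = 0.0
    n_high = h.sum()
    i = 0
    n_left = float(n)
    h_left = float(n_high)
    while i < n:
        j = i
        d = 0.0
        dh = 0.0
        while j < n and t[j] == t[i]:
            if e[j] == 1:
                d += 1.0
                dh += h[j]
            j += 1
        if d > 0 and n_left > 1:
            O += dh
            E += d * h_left / n_left
            V += d * (h_left / n_left) * (1 - h_left / n_left) * (n_left - d) / (n_left - 1)
        n_left -= j - i
        h_left -= h[i:j].sum()
        i = j
    if V <= 0:
        return 0.0
    return (O - E) / np.sqrt(V)


def optimal_cutpoint(marker, outcome: SurvivalOutcome,
                     minprop: float = 0.1) -> CutpointResult:
    """Maximally selected log-rank cut-point.

    Scans every admissible midpoint between consecutive distinct marker
    values (both resulting groups >= minprop * n) and returns the cut
    maximizing the absolute standardized two-group log-rank statistic.

    The p-value of a log-rank test at the selected cut is optimistically
    biased by the selection; this function reports the statistic only and
    emits a warning to that effect.
    """
    marker = np.asarray(marker, dtype=float)
    n = marker.size
    if marker.size != outcome.n:
        raise ValueError("marker and outcome must align")
    svals = np.sort(np.unique(marker))
    if svals.size < 2:
        raise ValueError("need at least 2 distinct marker values")
    mids = (svals[:-1] + svals[1:]) / 2.0
    lo_sizes = np.searchsorted(np.sort(marker), mids, side="right")
    min_n = minprop * n
    admissible = (lo_sizes >= min_n) & (n - lo_sizes >= min_n)
    if not admissible.any():
        raise ValueError(f"no admissible split at minprop={minprop}")
    rows = []
    for c in mids[admissible]:
        z = _two_group_logrank_z(marker > c, outcome.time, outcome.event)
        rows.append((c, z))
    scan = pd.DataFrame(rows, columns=["cutpoint", "z"])
    best = scan.loc[scan["z"].abs().idxmax()]
    cut = float(best["cutpoint"])
    warnings.warn(
        "optimal cut-point selection inflates the type-I error of a log-rank "
        "test at the selected cut; interpret p-values with caution",
        stacklevel=2,
    )
    return CutpointResult(
        cutpoint=cut,
        max_standardized_statistic=float(abs(best["z"])),
        group_sizes=(int((marker <= cut).sum()), int((marker > cut).sum())),
        minprop=minprop,
        scan=scan,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier & log-rank


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("KM survival must be non-increasing")
        if self.survival.size and not (0 <= self.survival.min()
                                       and self.survival.max() <= 1):
            raise ValueError("KM survival must lie in [0, 1]")

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(outcome: SurvivalOutcome) -> KMCurve:
    """Product-limit estimator; steps at the distinct event times."""
    if outcome.n < 1:
        raise ValueError("empty outcome")
    km = KaplanMeierFitter().fit(outcome.time, outcome.event)
    tab = km.event_table.iloc[1:] if km.event_table.index[0] == 0 else km.event_table
    tab = tab[tab["observed"] > 0]
    times = tab.index.to_numpy(float)
    surv = km.predict(times, interpolate=False).to_numpy(float)
    return KMCurve(times, surv, tab["at_risk"].to_numpy(int),
                   tab["observed"].to_numpy(int))


def logrank_test(groups, outcome: SurvivalOutcome):
    """k-group log-rank test -> (chi2, df, p)."""
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank test requires >= 2 non-empty groups")
    res = multivariate_logrank_test(outcome.time, groups, outcome.event)
    return float(res.test_statistic), int(labels.size - 1), float(res.p_value)


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationTable:
    eval_time: float
    table: pd.DataFrame  # columns: group, predicted, observed, n

    def __post_init__(self) -> None:
        pred, obs = self.table["predicted"], self.table["observed"]
        if ((pred < -1e-9) | (pred > 1 + 1e-9)).any() or \
           ((obs < -1e-9) | (obs > 1 + 1e-9)).any():
            raise ValueError("predicted/observed survival must lie in [0, 1]")


def calibration(predicted_survival, outcome: SurvivalOutcome,
                eval_time: float, n_groups: int = 5, *,
                population_mode: bool = False) -> CalibrationTable:
    """Predicted-vs-observed survival at a horizon.

    Grouped mode bins samples by predicted survival into ``n_groups``
    quantile bins, pairing each bin's mean prediction with its KM estimate
    at ``eval_time`` (bins left without subjects at risk are merged with a
    neighbour). Population mode pairs the cohort-mean predicted survival
    with the full-sample KM value — the form appropriate for opaque
    machine-learning models.
    """
    pred = np.asarray(predicted_survival, dtype=float)
    if pred.size != outcome.n:
        raise ValueError("predictions and outcome must align")
    if (pred < 0).any() or (pred > 1).any():
        raise ValueError("predictions must be survival probabilities in [0, 1]")
    if population_mode:
        obs = km_curve(outcome).at(eval_time)
        tab = pd.DataFrame({"group": ["population"], "predicted": [pred.mean()],
                            "observed": [obs], "n": [outcome.n]})
        return CalibrationTable(eval_time, tab)
    ranks = pd.Series(pred).rank(method="first")
    bins = pd.qcut(ranks, q=min(n_groups, outcome.n), labels=False)
    rows = []
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        sub = outcome.subset(idx)
        if (sub.time > eval_time).sum() == 0 and sub.n_events == 0:
            warnings.warn(f"calibration bin {b} empty at risk; merged", stacklevel=2)
            continue
        rows.append({"group": int(b), "predicted": pred[idx].mean(),
                     "observed": km_curve(sub).at(eval_time), "n": idx.size})
    return CalibrationTable(eval_time, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Bonferroni


@dataclass
class BonferroniResult:
    alpha: float
    m: int
    threshold: float
    significant: np.ndarray

    def __post_init__(self) -> None:
        self.significant = np.asarray(self.significant, dtype=bool)


def bonferroni_adjust(p_values, m: int, alpha: float = 0.05) -> BonferroniResult:
    """Bonferroni decisions: significant iff p < alpha / m.

    With alpha=0.05 and m=3 the threshold is 0.0167 (displayed 0.017).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    threshold = alpha / m
    return BonferroniResult(alpha, m, threshold, p < threshold)
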