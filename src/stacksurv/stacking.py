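"""Stacking of survival sub-models into one weighted linear predictor.

The ensemble proceeds in the classic stacking steps: (1) split the training
cohort into K event-stratified folds; (2) fit each refittable sub-model on
K-1 folds and compute its linear predictor on the held-out fold (fixed,
externally published signatures are evaluated directly); (3) stack the
out-of-fold linear predictors against the observed outcome; (4-5) maximize
the Cox partial likelihood of the outcome on the stacked columns under a
non-negativity constraint on the weights, via L-BFGS-B with analytic
gradient; (6) combine full-data sub-model linear predictors with the
normalized weights into the stacking linear predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cox import CoxData, cox_loglik
from .signature import risk_score
from .types import ExpressionMatrix, GeneSignature, SurvivalOutcome

__all__ = [
    "FoldAssignment", "SubModelSpec", "OofMatrix", "StackingWeights",
    "make_folds", "oof_linear_predictors", "fit_stacking_weights",
    "stacking_lp",
]


@dataclass
class FoldAssignment:
    sample_ids: list
    fold: np.ndarray  # 1..K
    K: int
    rng_seed: int

    def __post_init__(self) -> None:
        self.fold = np.asarray(self.fold, dtype=int)
        sizes = np.bincount(self.fold, minlength=self.K + 1)[1:]
        if sizes.sum() != len(self.sample_ids):
            raise ValueError("folds must partition the samples")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.fold, minlength=self.K + 1)[1:]


@dataclass
class SubModelSpec:
    """A stacking sub-model: either a fixed published signature or a
    refittable recipe ``fit(expr, outcome) -> GeneSignature``."""

    id: str
    kind: str  # "fixed_signature" | "refittable_signature"
    definition: Union[GeneSignature, Callable]

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_signature", "refittable_signature"):
            raise ValueError(f"unknown sub-model kind {self.kind!r}")
        if self.kind == "fixed_signature" and not isinstance(
            self.definition, GeneSignature
        ):
            raise ValueError("fixed_signature requires a GeneSignature definition")
        if self.kind == "refittable_signature" and not callable(self.definition):
            raise ValueError("refittable_signature requires a fitting callable")


@dataclass
class OofMatrix:
    sample_ids: list
    lp: pd.DataFrame  # samples x sub-models; NaN = failed fold entries
    fold_train_indices: Optional[dict] = None  # fold -> training row indices

    @property
    def submodel_ids(self) -> list:
        return list(self.lp.columns)


@dataclass
class StackingWeights:
    submodel_ids: list
    w: np.ndarray
    normalized: bool
    converged: bool = True
    loglik: float = np.nan

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if (self.w < 0).any():
            raise ValueError("stacking weights must be non-negative")
        if self.normalized and abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("normalized weights must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.w, index=self.submodel_ids, name="weight")


def make_folds(outcome: SurvivalOutcome, K: int = 10,
               rng_seed: int = 0) -> FoldAssignment:
    """Random balanced K-fold partition, event-stratified, with every fold
    guaranteed at least one event (resampled up to 100 attempts)."""
    n = outcome.n
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < K:
        raise ValueError("need at least K samples")
    rng = np.random.default_rng(rng_seed)
    for _ in range(100):
        fold = np.empty(n, dtype=int)
        # event-stratified balanced assignment
        offset = 0
        for grp in (np.flatnonzero(outcome.event == 1),
                    np.flatnonzero(outcome.event == 0)):
            perm = rng.permutation(grp)
            fold[perm] = (np.arange(perm.size) + offset) % K + 1
            offset += perm.size
        events_per_fold = np.bincount(fold[outcome.event == 1], minlength=K + 1)[1:]
        sizes = np.bincount(fold, minlength=K + 1)[1:]
        if (events_per_fold >= 1).all() and sizes.max() - sizes.min() <= 1:
            return FoldAssignment(list(outcome.sample_ids), fold, K, rng_seed)
    raise ValueError(
        f"could not build {K} folds with >=1 event each after 100 attempts"
    )


def oof_linear_predictors(submodels, expr: ExpressionMatrix,
                          outcome: SurvivalOutcome,
                          folds: FoldAssignment) -> OofMatrix:
    """Out-of-fold linear predictor of each sub-model.

    Refittable sub-models are retrained K times, each time on the K-1
    training folds, and evaluated on the held-out fold only; fixed
    signatures have no fold dependence and are evaluated directly. A fit
    failure in a fold leaves that fold's entries NaN (excluded downstream)
    with a warning.
    """
    expr_aligned = expr.subset_samples(outcome.sample_ids)
    n = outcome.n
    lp = pd.DataFrame(np.nan, index=outcome.sample_ids,
                      columns=[s.id for s in submodels])
    train_idx = {}
    for spec in submodels:
        if spec.kind == "fixed_signature":
            lp[spec.id] = risk_score(spec.definition, expr_aligned).score
            continue
        for k in range(1, folds.K + 1):
            held = folds.fold == k
            train = ~held
            train_idx.setdefault(k, np.flatnonzero(train))
            try:
                sig = spec.definition(
                    expr_aligned.subset_samples(
                        [outcome.sample_ids[i] for i in np.flatnonzero(train)]
                    ),
                    outcome.subset(train),
                )
                held_ids = [outcome.sample_ids[i] for i in np.flatnonzero(held)]
                lp.loc[held_ids, spec.id] = risk_score(
                    sig, expr_aligned.subset_samples(held_ids)
                ).score
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(
                    f"sub-model {spec.id!r} failed in fold {k}: {exc}; "
                    "entries flagged missing", stacklevel=2,
                )
    assert n == lp.shape[0]
    return OofMatrix(list(outcome.sample_ids), lp, train_idx or None)


def fit_stacking_weights(oof: OofMatrix, outcome: SurvivalOutcome,
                         normalize: bool = True) -> StackingWeights:
    """Non-negative Cox meta-fit of the sub-model weights.

    Maximizes the Breslow partial likelihood of the outcome on the
    out-of-fold columns subject to w_m >= 0, by L-BFGS-B with the analytic
    score as gradient (start w = 1/M, bounds [0, 10M], projected-gradient
    tolerance 1e-6). With ``normalize`` the weights are rescaled to sum to
    one; an all-zero optimum is rejected.
    """
    if len(oof.submodel_ids) < 1:
        raise ValueError("at least one sub-model column required")
    keep = ~oof.lp.isna().any(axis=1).to_numpy()
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} samples with missing OOF entries excluded from "
            "the meta-fit", stacklevel=2,
        )
    sub_outcome = outcome.align(list(oof.lp.index[keep]))
    if sub_outcome.n_events < 2:
        raise ValueError("meta-fit requires at least 2 events")
    M = len(oof.submodel_ids)
    X = oof.lp.to_numpy(float)[keep]
    data = CoxData(sub_outcome.time, sub_outcome.event)
    Xs = data.sort(X)

    def negloglik(w):
        ll, score = cox_loglik(data, Xs, w, order=1)
        return -ll, -score

    res = minimize(
        negloglik, x0=np.full(M, 1.0 / M), jac=True, method="L-BFGS-B",
        bounds=[(0.0, 10.0 * M)] * M, options={"gtol": 1e-6, "ftol": 1e-11, "maxiter": 500},
    )
    if not res.success:
        warnings.warn(f"stacking weight optimizer: {res.message}; best iterate "
                      "returned", stacklevel=2)
    w = np.maximum(res.x, 0.0)
    total = w.sum()
    if normalize:
        if total <= 1e-12:
            raise ValueError(
                "all stacking weights are zero at the optimum; no sub-model "
                "carries signal — cannot normalize"
            )
        w = w / total
    return StackingWeights(list(oof.submodel_ids), w, normalized=normalize,
                           converged=bool(res.success), loglik=float(-res.fun))


def stacking_lp(weights: StackingWeights, lps) -> np.ndarray:
    """Exact weighted sum sum_m w_m * lp_m per sample.

    ``lps`` is an array/DataFrame of shape (n_samples, M) or a length-M
    vector for a single sample.
    """
    arr = np.asarray(lps, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.shape[1] != weights.w.size:
        raise ValueError(
            f"dimension mismatch: {arr.shape[1]} linear predictors vs "
            f"{weights.w.size} weights"
        )
    out = arr @ weights.w
    return float(out[0]) if single else out
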