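"""Machine-learning final model on {stacking linear predictor, age, FAB}.

Four survival learners — random survival forest, survival SVM, gradient
boosting and XGBoost with a Cox objective — are exposed through a uniform
adapter contract (fit / predict_risk / predict_survival). Learners whose
backend emits only a risk score (SVM, XGBoost) are calibrated to a survival
function by a univariate Cox refit on the score with a Breslow baseline, so
every fitted model honours the survival-function contract: S(0) = 1,
non-increasing, values in [0, 1].

The bespoke logic here is the tuning (10-fold grid search on Harrell's
concordance), selection by cross-validated time-dependent AUC, bootstrap
internal validation with out-of-bag evaluation, and the contracts; the
learners themselves come from scikit-survival and xgboost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sksurv.metrics import concordance_index_censored

from .cox import breslow_cumhazard, cumhazard_at, fit_cox
from .evaluation import td_roc
from .types import ClinicalTable, SurvivalOutcome

__all__ = [
    "LearnerSpec", "FittedFinalModel", "BootstrapReport", "build_features",
    "train_learner", "select_learner", "bootstrap_validate",
    "predict_death_probability", "LEARNER_REGISTRY", "default_specs",
]

EVAL_TIMES_DEFAULT = (365.0, 730.0, 1095.0)  # 1, 2, 3 years in days


def build_features(stacking_lp, clinical: ClinicalTable,
                   sample_ids=None) -> pd.DataFrame:
    """Feature frame {stacking_lp, age, one-hot FAB (largest level as
    reference)}; clinical values must be complete (post-imputation)."""
    if sample_ids is None:
        sample_ids = clinical.sample_ids
    clin = clinical.align(sample_ids).data
    if clin[["age", "fab"]].isna().any().any():
        raise ValueError("clinical covariates contain missing values; impute first")
    lp = np.asarray(stacking_lp, dtype=float)
    if lp.size != len(sample_ids):
        raise ValueError("stacking_lp and samples must align")
    out = pd.DataFrame({"stacking_lp": lp, "age": clin["age"].to_numpy(float)},
                       index=sample_ids)
    fab = clin["fab"].astype(int)
    ref = fab.value_counts().idxmax()
    for lvl in sorted(fab.unique()):
        if lvl == ref:
            continue
        out[f"fab_{lvl}"] = (fab == lvl).astype(float).to_numpy()
    return out


# ---------------------------------------------------------------------------
# adapters


class _CoxCalibrated:
    """Wrap a raw risk score with a univariate Cox refit + Breslow baseline,
    yielding an oriented, scaled survival function."""

    def __init__(self, score_fn):
        self.score_fn = score_fn

    def calibrate(self, X, outcome: SurvivalOutcome):
        s = np.asarray(self.score_fn(X), dtype=float)
        sd = s.std()
        self._scale = sd if sd > 0 else 1.0
        self._center = s.mean()
        z = (s - self._center) / self._scale
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_cox(z[:, None], outcome)
        self._beta = float(fit.beta[0])
        eta = self._beta * z
        self._bl_times, self._bl_H0 = breslow_cumhazard(eta, outcome)

    def survival(self, X, times):
        z = (np.asarray(self.score_fn(X), float) - self._center) / self._scale
        eta = self._beta * z
        H0 = cumhazard_at(self._bl_times, self._bl_H0, times)
        return np.exp(-np.outer(np.exp(eta), H0))  # samples x times


class _RsfAdapter:
    name = "rsf"
    default_grid = {"n_estimators": [100], "min_samples_leaf": [5, 15]}

    def __init__(self, rng_seed=0, **params):
        from sksurv.ensemble import RandomSurvivalForest

        self.model = RandomSurvivalForest(random_state=rng_seed, n_jobs=1,
                                          **params)

    def fit(self, X, outcome):
        self.model.fit(np.asarray(X, float), outcome.to_structured())
        return self

    def predict_risk(self, X):
        return self.model.predict(np.asarray(X, float))

    def predict_survival(self, X, times):
        fns = self.model.predict_survival_function(np.asarray(X, float))
        return _eval_step_functions(fns, times)


def _eval_step_functions(fns, times):
    """Evaluate sksurv StepFunctions, extending them as constants outside
    their domain (S=1 before the first event, flat after the last)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.empty((len(fns), times.size))
    for i, fn in enumerate(fns):
        first_jump = fn.x[0]
        lo, hi = fn.domain if hasattr(fn, "domain") else (fn.x[0], fn.x[-1])
        t = np.clip(times, max(lo, first_jump), hi)
        out[i] = fn(t)
        out[i, times < first_jump] = 1.0
    return out


class _GbmAdapter:
    name = "gbm"
    default_grid = {"n_estimators": [100], "max_depth": [2, 3],
                    "learning_rate": [0.1]}

    def __init__(self, rng_seed=0, **params):
        from sksurv.ensemble import GradientBoostingSurvivalAnalysis

        self.model = GradientBoostingSurvivalAnalysis(random_state=rng_seed,
                                                      **params)

    def fit(self, X, outcome):
        self.model.fit(np.asarray(X, float), outcome.to_structured())
        return self

    def predict_risk(self, X):
        return self.model.predict(np.asarray(X, float))

    def predict_survival(self, X, times):
        fns = self.model.predict_survival_function(np.asarray(X, float))
        return _eval_step_functions(fns, times)


class _SvmAdapter:
    name = "survival_svm"
    default_grid = {"alpha": [0.01, 1.0, 100.0]}

    def __init__(self, rng_seed=0, **params):
        from sksurv.svm import FastSurvivalSVM

        params.setdefault("max_iter", 100)
        self.model = FastSurvivalSVM(random_state=rng_seed, rank_ratio=1.0,
                                     **params)
        self._cal = None

    def fit(self, X, outcome):
        X = np.asarray(X, float)
        self.model.fit(X, outcome.to_structured())
        # FastSurvivalSVM scores are anti-concordant with risk; the Cox
        # calibration learns orientation and scale from the data.
        self._cal = _CoxCalibrated(lambda A: self.model.predict(np.asarray(A, float)))
        self._cal.calibrate(X, outcome)
        return self

    def predict_risk(self, X):
        z = (np.asarray(self.model.predict(np.asarray(X, float)), float)
             - self._cal._center) / self._cal._scale
        return self._cal._beta * z

    def predict_survival(self, X, times):
        return self._cal.survival(X, times)


class _XgbAdapter:
    name = "xgboost_cox"
    default_grid = {"max_depth": [2, 3], "learning_rate": [0.1],
                    "n_rounds": [100]}

    def __init__(self, rng_seed=0, n_rounds=100, **params):
        self.params = {
            "objective": "survival:cox", "nthread": 1, "seed": int(rng_seed),
            "max_depth": 2, "learning_rate": 0.1, **params,
        }
        self.n_rounds = int(n_rounds)
        self._cal = None

    def fit(self, X, outcome):
        import xgboost as xgb

        X = np.asarray(X, float)
        # survival:cox encodes censoring as negative times
        y = np.where(outcome.event == 1, outcome.time, -outcome.time)
        dtrain = xgb.DMatrix(X, label=y)
        self.booster = xgb.train(self.params, dtrain,
                                 num_boost_round=self.n_rounds)
        self._cal = _CoxCalibrated(self._margin)
        self._cal.calibrate(X, outcome)
        return self

    def _margin(self, X):
        import xgboost as xgb

        return self.booster.predict(xgb.DMatrix(np.asarray(X, float)),
                                    output_margin=True)

    def predict_risk(self, X):
        return self._margin(X)

    def predict_survival(self, X, times):
        return self._cal.survival(X, times)


LEARNER_REGISTRY = {
    "rsf": _RsfAdapter,
    "survival_svm": _SvmAdapter,
    "gbm": _GbmAdapter,
    "xgboost_cox": _XgbAdapter,
}


@dataclass
class LearnerSpec:
    name: str
    hyperparameter_grid: dict = None
    cv_folds: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in LEARNER_REGISTRY:
            raise ValueError(
                f"learner {self.name!r} not in registry "
                f"{sorted(LEARNER_REGISTRY)}"
            )
        if self.hyperparameter_grid is None:
            self.hyperparameter_grid = dict(
                LEARNER_REGISTRY[self.name].default_grid
            )
        if not self.hyperparameter_grid:
            raise ValueError("hyperparameter grid must be non-empty")


def default_specs(rng_seed: int = 0, cv_folds: int = 10):
    return [LearnerSpec(name, rng_seed=rng_seed, cv_folds=cv_folds)
            for name in ("rsf", "survival_svm", "gbm", "xgboost_cox")]


@dataclass
class FittedFinalModel:
    learner: str
    adapter: object
    feature_names: list
    best_params: dict
    cv_scores: pd.DataFrame = None

    def predict_risk(self, features: pd.DataFrame):
        return self.adapter.predict_risk(self._mat(features))

    def predict_survival(self, features: pd.DataFrame, times):
        times = np.asarray(times, dtype=float)
        S = self.adapter.predict_survival(self._mat(features), times)
        return np.clip(S, 0.0, 1.0)

    def _mat(self, features: pd.DataFrame):
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        return features[self.feature_names].to_numpy(float)


def _grid_cells(grid: dict):
    keys = sorted(grid)
    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _cv_folds_idx(n, k, rng):
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def train_learner(spec: LearnerSpec, features: pd.DataFrame,
                  outcome: SurvivalOutcome) -> FittedFinalModel:
    """Grid-search a learner by K-fold CV on Harrell's concordance, then
    refit on all data at the best configuration. Deterministic under seed."""
    if features.isna().any().any():
        raise ValueError("features contain missing values; impute first")
    if outcome.n_events < 2:
        raise ValueError("training requires at least 2 events")
    X = features.to_numpy(float)
    n = X.shape[0]
    rng = np.random.default_rng(spec.rng_seed)
    k = min(spec.cv_folds, n)
    folds = _cv_folds_idx(n, k, rng)
    rows = []
    for cell in _grid_cells(spec.hyperparameter_grid):
        scores = []
        for held in folds:
            train = np.setdiff1d(np.arange(n), held)
            sub = outcome.subset(train)
            if sub.n_events < 2 or outcome.event[held].sum() < 1:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ad = LEARNER_REGISTRY[spec.name](rng_seed=spec.rng_seed,
                                                     **cell)
                    ad.fit(X[train], sub)
                    risk = ad.predict_risk(X[held])
                c = concordance_index_censored(
                    outcome.event[held].astype(bool), outcome.time[held], risk
                )[0]
                scores.append(c)
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"{spec.name} grid cell {cell} failed in a fold: "
                              f"{exc}", stacklevel=2)
        rows.append({"params": cell,
                     "mean_concordance": float(np.mean(scores)) if scores else np.nan})
    table = pd.DataFrame(rows)
    if table["mean_concordance"].isna().all():
        raise ValueError(f"every grid cell failed for learner {spec.name!r}")
    best = table.loc[table["mean_concordance"].idxmax(), "params"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adapter = LEARNER_REGISTRY[spec.name](rng_seed=spec.rng_seed, **best)
        adapter.fit(X, outcome)
    return FittedFinalModel(spec.name, adapter, list(features.columns), best,
                            table)


def _cv_td_auc(spec: LearnerSpec, features: pd.DataFrame,
               outcome: SurvivalOutcome, eval_times, k: int = 5) -> float:
    """Mean out-of-fold time-dependent AUC over eval_times (pooled OOF risk).

    Uses the first grid cell of the spec: selection compares the learners'
    crude performance, the winner is tuned afterwards by train_learner.
    """
    X = features.to_numpy(float)
    n = X.shape[0]
    rng = np.random.default_rng(spec.rng_seed)
    folds = _cv_folds_idx(n, k, rng)
    oof = np.full(n, np.nan)
    cell = {key: vals[0] for key, vals in spec.hyperparameter_grid.items()}
    for held in folds:
        train = np.setdiff1d(np.arange(n), held)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ad = LEARNER_REGISTRY[spec.name](rng_seed=spec.rng_seed, **cell)
            ad.fit(X[train], outcome.subset(train))
            oof[held] = ad.predict_risk(X[held])
    aucs = [td_roc(oof, outcome, t).auc for t in sorted(eval_times)]
    return float(np.mean(aucs))


def select_learner(specs, features: pd.DataFrame, outcome: SurvivalOutcome,
                   eval_times=EVAL_TIMES_DEFAULT):
    """Score each learner by cross-validated time-dependent AUC and return
    (best FittedFinalModel name, per-learner AUC table). Ties break toward
    the earlier learner in registry order."""
    if len(specs) < 2:
        raise ValueError("learner selection requires >= 2 candidates")
    registry_order = list(LEARNER_REGISTRY)
    rows = []
    for spec in specs:
        try:
            auc = _cv_td_auc(spec, features, outcome, eval_times)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"learner {spec.name} failed selection: {exc}",
                          stacklevel=2)
            auc = np.nan
        rows.append({"learner": spec.name, "mean_td_auc": auc,
                     "_order": registry_order.index(spec.name)})
    table = pd.DataFrame(rows)
    if table["mean_td_auc"].isna().all():
        raise ValueError("all learners failed")
    ok = table.dropna(subset=["mean_td_auc"])
    best = ok.sort_values(["mean_td_auc", "_order"],
                          ascending=[False, True]).iloc[0]["learner"]
    return str(best), table.drop(columns="_order")


@dataclass
class BootstrapReport:
    B: int
    statistic: str
    mean: float
    ci95: tuple
    values: np.ndarray
    n_skipped: int = 0


def bootstrap_validate(fit_fn, features: pd.DataFrame,
                       outcome: SurvivalOutcome, B: int = 1000,
                       eval_times=EVAL_TIMES_DEFAULT,
                       rng_seed: int = 0) -> BootstrapReport:
    """Bootstrap internal validation with out-of-bag evaluation.

    Each replicate resamples n samples with replacement, refits via
    ``fit_fn(features, outcome) -> FittedFinalModel``, and evaluates the
    mean time-dependent AUC over ``eval_times`` on the out-of-bag samples.
    Reports the mean and the percentile 2.5/97.5 CI; replicates whose OOB
    set lacks cases or controls are skipped and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = outcome.n
    rng = np.random.default_rng(rng_seed)
    values = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), np.unique(idx))
        if oob.size == 0:
            skipped += 1
            continue
        # resampling creates duplicate sample ids; relabel
        boot_out = SurvivalOutcome(
            [f"b{i}" for i in range(n)], outcome.time[idx], outcome.event[idx]
        )
        boot_feat = features.iloc[idx].set_axis([f"b{i}" for i in range(n)])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_fn(boot_feat, boot_out)
                risk = model.predict_risk(features.iloc[oob])
            aucs = [td_roc(risk, outcome.subset(oob), t).auc
                    for t in sorted(eval_times)]
            values.append(float(np.mean(aucs)))
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
    if not values:
        raise ValueError("every bootstrap replicate was skipped")
    values = np.asarray(values)
    lo, hi = (values[0], values[0]) if values.size == 1 else (
        float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5))
    )
    return BootstrapReport(B, f"mean td-AUC over {tuple(sorted(eval_times))}",
                           float(values.mean()), (lo, hi), values, skipped)


def predict_death_probability(model: FittedFinalModel,
                              patient_features: pd.DataFrame, times):
    """1 - S(t|x) at ascending positive times; 0 at t=0 by convention."""
    times = np.asarray(times, dtype=float)
    if (times < 0).any() or np.any(np.diff(times) < 0):
        raise ValueError("times must be non-negative and ascending")
    S = model.predict_survival(patient_features, np.maximum(times, 1e-12))
    death = 1.0 - S
    death[:, times == 0] = 0.0
    # enforce monotone non-decreasing death probability across times
    death = np.maximum.accumulate(death, axis=1)
    return np.clip(death, 0.0, 1.0)
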