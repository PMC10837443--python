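"""Sparse Cox gene-signature construction.

The signature stage takes the univariate-screen survivors through
(1) spike-and-slab lasso Cox selection — an EM coordinate-ascent over the
penalized partial likelihood with a two-component double-exponential prior
(narrow spike scale s0, wide slab scale s1, prior inclusion probability
theta), with the spike scale chosen by the cross-validated partial
log-likelihood (CVPL, Verweij-van Houwelingen); (2) bidirectional stepwise
AIC on the unpenalized Cox model; and (3) the risk-score formula
``score_j = sum_i beta_i * Exp_ij``. A Grambsch-Therneau test of the
proportional-hazards assumption is provided as an advisory check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxData, cox_loglik, fit_cox, schoenfeld_residuals
from .types import ExpressionMatrix, GeneSignature, RiskScoreVector, SurvivalOutcome

__all__ = [
    "SelectionConfig", "SslassoResult", "PhTestResult",
    "sslasso_select", "stepwise_aic", "risk_score", "ph_test",
    "load_published_signature",
]


def load_published_signature() -> GeneSignature:
    """The published 14-gene cuproptosis-related signature shipped with the
    package (gene, Cox coefficient) pairs."""
    ref = resources.files("stacksurv.data").joinpath("published_signature_crg14.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return GeneSignature(df["gene"].tolist(), df["coefficient"].to_numpy(float),
                         provenance="published 14-gene CRG signature")


# ---------------------------------------------------------------------------
# spike-and-slab lasso


@dataclass
class SelectionConfig:
    s0_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.005, 1.0, 16)
    )
    s1: float = 1.0
    theta: float = 0.5
    cv_folds: int = 10
    cv_replicates: int = 10
    rng_seed: int = 0
    max_em_iter: int = 200
    tol: float = 1e-4

    def __post_init__(self) -> None:
        self.s0_grid = np.asarray(self.s0_grid, dtype=float)
        if self.s0_grid.size == 0:
            raise ValueError("s0_grid must be non-empty")
        if (self.s0_grid <= 0).any() or (self.s0_grid > self.s1).any():
            raise ValueError("every s0 must satisfy 0 < s0 <= s1")
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")


@dataclass
class SslassoResult:
    selected_genes: list
    betas: np.ndarray
    s0_opt: float
    cvpl_by_s0: pd.Series
    full_beta: np.ndarray
    candidate_genes: list
    converged: bool


def _soft(x: float, lam: float) -> float:
    return np.sign(x) * max(abs(x) - lam, 0.0)


def _wl1_cox_cd(data: CoxData, Xs: np.ndarray, lam: np.ndarray,
                beta0: np.ndarray, tol: float = 1e-5,
                max_cycles: int = 200) -> np.ndarray:
    """Coordinate descent for the L1-penalized Cox partial likelihood
    -loglik(beta) + sum_j lam_j * |beta_j| (coordinate-wise Newton with
    soft-thresholding; per-update change capped for stability)."""
    n, p = Xs.shape
    beta = beta0.copy()
    eta = Xs @ beta
    x_death_sum = Xs[data.death_idx].sum(axis=0)
    for _ in range(max_cycles):
        delta_max = 0.0
        shift = eta.max()
        w = np.exp(eta - shift)
        cw = np.cumsum(w)
        for j in range(p):
            g, h = _coord_derivs(data, Xs[:, j], w, cw, x_death_sum[j])
            if h <= 1e-12:
                continue
            bj = beta[j]
            bj_new = _soft(h * bj + g, lam[j]) / h
            step = np.clip(bj_new - bj, -5.0, 5.0)
            bj_new = bj + step
            if bj_new != bj:
                eta = eta + Xs[:, j] * (bj_new - bj)
                # refresh risk weights after the coordinate move
                shift = eta.max()
                w = np.exp(eta - shift)
                cw = np.cumsum(w)
                delta_max = max(delta_max, abs(bj_new - bj))
                beta[j] = bj_new
        if delta_max < tol:
            break
    return beta


def _coord_derivs(data: CoxData, x: np.ndarray, w: np.ndarray,
                  cw: np.ndarray, x_death_sum: float):
    """Gradient and (positive) curvature of the Breslow partial likelihood
    with respect to one coordinate, given risk weights w = exp(eta - max)."""
    ends = data.event_group_end
    d = data.event_group_d
    xw = x * w
    cxw = np.cumsum(xw)
    cxxw = np.cumsum(x * xw)
    S0 = cw[ends]
    xbar = cxw[ends] / S0
    g = x_death_sum - d @ xbar
    h = d @ (cxxw[ends] / S0 - xbar * xbar)
    return g, h


def _em_sslasso(data: CoxData, Xs: np.ndarray, s0: float, s1: float,
                theta: float, max_iter: int, tol: float,
                beta0: np.ndarray = None):
    """EM coordinate-ascent for the spike-and-slab lasso Cox model.

    E-step: posterior slab probability p_j of each coefficient under the
    double-exponential mixture prior; M-step: weighted L1-penalized Cox
    update with per-coefficient scale S_j = (1-p_j)*s0 + p_j*s1
    (penalty rate 1/S_j). Warm-startable via ``beta0``.
    """
    p = Xs.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    converged = False
    for _ in range(max_iter):
        dens0 = np.exp(-np.abs(beta) / s0) / (2.0 * s0)
        dens1 = np.exp(-np.abs(beta) / s1) / (2.0 * s1)
        post = theta * dens1 / (theta * dens1 + (1.0 - theta) * dens0)
        scale = (1.0 - post) * s0 + post * s1
        lam = 1.0 / scale
        beta_new = _wl1_cox_cd(data, Xs, lam, beta, max_cycles=25)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return beta, converged


def _stratified_folds(event: np.ndarray, k: int, rng: np.random.Generator):
    """Fold labels 0..k-1 stratified by event status."""
    n = event.size
    fold = np.empty(n, dtype=int)
    for grp in (np.flatnonzero(event == 1), np.flatnonzero(event == 0)):
        perm = rng.permutation(grp)
        fold[perm] = np.arange(perm.size) % k
    return fold


def sslasso_select(expr_subset: ExpressionMatrix, outcome: SurvivalOutcome,
                   config: SelectionConfig) -> SslassoResult:
    """Spike-and-slab lasso Cox selection with CVPL-tuned spike scale.

    For each s0 on the grid, the cross-validated partial log-likelihood
    CVPL(s0) = sum_k [ l(beta_(-k); full) - l(beta_(-k); data minus fold k) ]
    is averaged over ``cv_replicates`` random ``cv_folds``-fold splits
    (event-stratified); the maximizing s0 is refit on all data. Genes with
    nonzero coefficients are returned; an empty selection is a valid outcome
    reported with diagnostics, not an error.
    """
    if expr_subset.n_genes < 2:
        raise ValueError("sslasso_select requires at least 2 candidate genes")
    expr_aligned = expr_subset.subset_samples(outcome.sample_ids)
    X = expr_aligned.values.T  # samples x genes
    genes = expr_aligned.gene_ids
    data = CoxData(outcome.time, outcome.event)
    Xs = data.sort(X)
    rng = np.random.default_rng(config.rng_seed)

    cvpl = np.zeros(config.s0_grid.size)
    for rep in range(config.cv_replicates):
        fold = _stratified_folds(outcome.event, config.cv_folds, rng)
        for k in range(config.cv_folds):
            mask = fold != k
            sub = outcome.subset(mask)
            data_k = CoxData(sub.time, sub.event)
            Xk = data_k.sort(X[mask])
            warm = None
            # descend the grid from the weakest spike, warm-starting
            for si in np.argsort(-config.s0_grid):
                s0 = config.s0_grid[si]
                beta_k, _ = _em_sslasso(data_k, Xk, s0, config.s1,
                                        config.theta, config.max_em_iter,
                                        config.tol, beta0=warm)
                warm = beta_k
                l_full = cox_loglik(data, Xs, beta_k, order=0)
                l_train = cox_loglik(data_k, Xk, beta_k, order=0)
                cvpl[si] += l_full - l_train
    cvpl /= config.cv_replicates
    s0_opt = float(config.s0_grid[int(np.argmax(cvpl))])

    beta, converged = _em_sslasso(data, Xs, s0_opt, config.s1, config.theta,
                                  config.max_em_iter, config.tol)
    if not converged:
        warnings.warn("spike-and-slab EM did not converge; best iterate returned",
                      stacklevel=2)
    nz = np.abs(beta) > 1e-10
    return SslassoResult(
        selected_genes=[g for g, keep in zip(genes, nz) if keep],
        betas=beta[nz],
        s0_opt=s0_opt,
        cvpl_by_s0=pd.Series(cvpl, index=config.s0_grid, name="cvpl"),
        full_beta=beta,
        candidate_genes=genes,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# stepwise AIC


def _cox_aic(X: np.ndarray, outcome: SurvivalOutcome) -> float:
    if X.shape[1] == 0:
        data = CoxData(outcome.time, outcome.event)
        return -2.0 * cox_loglik(data, np.zeros((data.n, 1)), np.zeros(1), order=0)
    fit = fit_cox(X, outcome)
    return -2.0 * fit.loglik + 2.0 * X.shape[1]


def stepwise_aic(expr_subset: ExpressionMatrix, outcome: SurvivalOutcome,
                 start_genes) -> GeneSignature:
    """Bidirectional stepwise Cox selection minimizing AIC = -2*loglik + 2k.

    Starts from the full ``start_genes`` set (the spike-and-slab survivors);
    at each step the single add or drop with the lowest AIC is taken, ties
    broken toward the smaller model; terminates when no move lowers the AIC.
    Returned coefficients are the final unpenalized Cox fit.
    """
    start_genes = list(start_genes)
    if not start_genes:
        raise ValueError("stepwise_aic requires at least one starting gene")
    expr_aligned = expr_subset.subset_genes(start_genes).subset_samples(
        outcome.sample_ids
    )
    mat = pd.DataFrame(expr_aligned.values.T, columns=start_genes)

    def aic_of(genes):
        try:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                return _cox_aic(mat[list(genes)].to_numpy(), outcome)
        except (ValueError, np.linalg.LinAlgError):
            warnings.warn(f"stepwise move to {sorted(genes)} failed; skipped",
                          stacklevel=2)
            return np.inf

    current = list(start_genes)
    current_aic = aic_of(current)
    while True:
        moves = []
        for gdrop in current:
            cand = [g for g in current if g != gdrop]
            moves.append((aic_of(cand), len(cand), cand))
        for gadd in (g for g in start_genes if g not in current):
            cand = current + [gadd]
            moves.append((aic_of(cand), len(cand), cand))
        if not moves:
            break
        moves.sort(key=lambda t: (round(t[0], 10), t[1]))
        best_aic, best_size, best = moves[0]
        improved = best_aic < current_aic - 1e-10
        tie_smaller = abs(best_aic - current_aic) <= 1e-10 and best_size < len(current)
        if improved or tie_smaller:
            current, current_aic = best, best_aic
            if not current:
                raise ValueError("stepwise AIC removed every gene (null model wins)")
        else:
            break
    fit = fit_cox(mat[current].to_numpy(), outcome)
    return GeneSignature(current, fit.beta, provenance="stepwise AIC Cox fit")


# ---------------------------------------------------------------------------
# risk score & proportional-hazards check


def risk_score(signature: GeneSignature, expr: ExpressionMatrix) -> RiskScoreVector:
    """Exact linear predictor sum_i beta_i * Exp_i per sample (no
    standardization, order independent)."""
    sub = expr.subset_genes(signature.genes)
    score = signature.betas @ sub.values
    return RiskScoreVector(sub.sample_ids, score)


@dataclass
class PhTestResult:
    per_covariate: dict  # name -> (rho, chi2, p)
    global_test: tuple  # (chi2, df, p)

    def to_frame(self) -> pd.DataFrame:
        rows = {k: {"rho": v[0], "chi2": v[1], "p": v[2]}
                for k, v in self.per_covariate.items()}
        df = pd.DataFrame(rows).T
        df.loc["GLOBAL"] = [np.nan, self.global_test[0], self.global_test[2]]
        return df


def ph_test(covariates, expr_or_none=None, outcome: SurvivalOutcome = None,
            transform: str = "km") -> PhTestResult:
    """Grambsch-Therneau test of the proportional-hazards assumption.

    Accepts either a covariate DataFrame (samples x covariates) or a
    :class:`GeneSignature` plus an expression matrix (the signature genes
    become the covariates of a refit Cox model). Schoenfeld residuals are
    correlated against the Kaplan-Meier transform of the event times
    (``transform='km'``; 'identity' and 'log' also supported); each
    covariate gets a score-type chi-square on 1 df, plus a global
    chi-square on #covariates df.
    """
    if isinstance(covariates, GeneSignature):
        if expr_or_none is None:
            raise ValueError("expression matrix required with a GeneSignature")
        sub = expr_or_none.subset_genes(covariates.genes).subset_samples(
            outcome.sample_ids
        )
        frame = pd.DataFrame(sub.values.T, columns=covariates.genes)
    else:
        frame = pd.DataFrame(covariates)
    if outcome is None:
        raise ValueError("outcome required")
    if outcome.n_events < 2:
        raise ValueError("PH test requires at least 2 events")
    X = frame.to_numpy(float)
    names = list(frame.columns)
    fit = fit_cox(X, outcome)
    times, resid = schoenfeld_residuals(X, outcome, fit.beta)
    d = times.size
    if transform == "km":
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(outcome.time, outcome.event)
        surv = km.predict(times, interpolate=False).to_numpy(float)
        g = 1.0 - surv
    elif transform == "identity":
        g = times.astype(float)
    elif transform == "log":
        g = np.log(times)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    u = gc @ resid  # p-vector
    info = np.linalg.inv(fit.covariance)  # observed information at beta-hat
    denom = float(gc @ gc)
    # per-covariate score-type statistic (df 1)
    per = {}
    for j, name in enumerate(names):
        chi2_j = d * u[j] ** 2 / (denom * info[j, j])
        rho = float(np.corrcoef(gc, resid[:, j])[0, 1]) if d > 1 else np.nan
        per[name] = (rho, float(chi2_j), float(stats.chi2.sf(chi2_j, 1)))
    chi2_g = float(d * u @ fit.covariance @ u / denom)
    p_g = float(stats.chi2.sf(chi2_g, len(names)))
    return PhTestResult(per, (chi2_g, len(names), p_g))
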