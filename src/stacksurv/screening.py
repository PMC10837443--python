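"""Seed-panel correlation screen and univariate Cox survival screen.

Two sequential filters reduce the transcriptome to survival-relevant,
seed-correlated candidates: (1) Spearman rank correlation of every non-seed
gene against each gene of the 10-gene cuproptosis seed panel, passing on
|Rs| > 0.4 and P < 0.05 versus *any* seed gene; (2) a per-gene univariate
Cox regression on overall survival, passing on Wald P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit, fit_cox
from .types import ExpressionMatrix, SurvivalOutcome

__all__ = [
    "ScreenConfig", "ScreenResult", "UnivariateCoxResult",
    "spearman_screen", "univariate_cox_screen", "fit_cox",
]


@dataclass
class ScreenConfig:
    seed_genes: list = field(default_factory=list)
    rs_threshold: float = 0.4
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.rs_threshold < 1:
            raise ValueError("rs_threshold must lie in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not self.seed_genes:
            raise ValueError("at least one seed gene required")


@dataclass
class ScreenResult:
    gene_id: str
    best_seed_gene: str
    rs: float
    p_value: float
    passed: bool
    constant: bool = False


@dataclass
class UnivariateCoxResult:
    gene_id: str
    beta: float
    hr: float
    ci95: tuple
    p_value: float
    passed: bool
    failed: bool = False


def _spearman_pvalue(rs: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation t = rs*sqrt((n-2)/(1-rs^2))."""
    rs = np.clip(rs, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rs * np.sqrt((n - 2) / (1.0 - rs**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rs) >= 1.0] = 0.0
    return p


def spearman_screen(expr: ExpressionMatrix, config: ScreenConfig):
    """Rank-correlate every non-seed gene against the seed panel.

    Spearman Rs is computed on average ranks (ties mid-ranked); a gene
    passes if |Rs| > rs_threshold and P < p_threshold against ANY seed gene.
    Constant genes have undefined Rs and are reported as not passed with the
    ``constant`` flag set.
    """
    n = expr.n_samples
    if n < 5:
        raise ValueError("correlation screen requires at least 5 samples")
    missing = [g for g in config.seed_genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"seed gene(s) absent from expression matrix: {missing}")
    values = expr.values
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    seed_rows = np.array([gene_index[g] for g in config.seed_genes])
    ranks = stats.rankdata(values, axis=1)
    sd = ranks.std(axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    # Rs = Pearson correlation of average ranks
    safe_sd = np.where(sd == 0, 1.0, sd)
    zr = centered / safe_sd[:, None]
    seed_ok = sd[seed_rows] > 0
    corr = zr @ zr[seed_rows].T / n  # genes x seeds
    corr[:, ~seed_ok] = 0.0
    pvals = _spearman_pvalue(corr, n)
    pvals[:, ~seed_ok] = 1.0

    seed_set = set(config.seed_genes)
    results = []
    for i, g in enumerate(expr.gene_ids):
        if g in seed_set:
            continue
        if sd[i] == 0:
            results.append(ScreenResult(g, "", np.nan, np.nan, False, constant=True))
            continue
        j = int(np.argmax(np.abs(corr[i])))
        rs, p = float(corr[i, j]), float(pvals[i, j])
        passed = bool(
            ((np.abs(corr[i]) > config.rs_threshold)
             & (pvals[i] < config.p_threshold)).any()
        )
        results.append(ScreenResult(g, config.seed_genes[j], rs, p, passed))
    return results


def univariate_cox_screen(expr: ExpressionMatrix, outcome: SurvivalOutcome,
                          p_threshold: float = 0.05, *,
                          standardize: bool = False):
    """Per-gene univariate Cox regression on overall survival.

    By default the fit is on raw log-scale expression, so hazard ratios are
    per unit log-expression; ``standardize=True`` z-scores each gene first.
    Per-gene fit failures are recorded (``failed=True``) without aborting
    the scan.
    """
    expr_aligned = expr.subset_samples(outcome.sample_ids)
    results = []
    for i, g in enumerate(expr_aligned.gene_ids):
        x = expr_aligned.values[i]
        if standardize:
            s = x.std()
            x = (x - x.mean()) / s if s > 0 else x
        try:
            if x.std() == 0:
                raise ValueError("constant gene")
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                fit: CoxFit = fit_cox(x[:, None], outcome)
            beta = float(fit.beta[0])
            se = float(fit.se[0])
            z = beta / se if se > 0 else np.inf
            p = float(2.0 * stats.norm.sf(abs(z)))
            ci = (float(np.exp(beta - 1.959963984540054 * se)),
                  float(np.exp(beta + 1.959963984540054 * se)))
            results.append(UnivariateCoxResult(
                g, beta, float(np.exp(beta)), ci, p, passed=p < p_threshold
            ))
        except (ValueError, np.linalg.LinAlgError):
            results.append(UnivariateCoxResult(
                g, np.nan, np.nan, (np.nan, np.nan), np.nan,
                passed=False, failed=True,
            ))
    return results


def screen_results_frame(spearman_results=None, cox_results=None) -> pd.DataFrame:
    """Tidy one-row-per-gene table of screen outputs (for TSV export)."""
    frames = []
    if spearman_results is not None:
        frames.append(pd.DataFrame([vars(r) for r in spearman_results]).set_index("gene_id"))
    if cox_results is not None:
        cf = pd.DataFrame([vars(r) for r in cox_results]).set_index("gene_id")
        cf = cf.rename(columns={"p_value": "cox_p_value", "passed": "cox_passed"})
        frames.append(cf)
    if not frames:
        raise ValueError("nothing to tabulate")
    return pd.concat(frames, axis=1)
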