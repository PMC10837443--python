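"""Reading/writing pipeline tables, cross-dataset quantile normalization and
missForest-style clinical imputation.

File dialects (gzip-transparent, delimiter configurable):

* expression — genes x samples, first column ``gene_id``, header = sample ids
* clinical — columns ``sample_id, time_days, event, age, fab, eln2017``
* signature — two columns ``gene, coefficient``
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .types import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSignature,
    SurvivalOutcome,
)

__all__ = [
    "read_expression", "write_expression", "read_clinical", "write_clinical",
    "read_signature", "write_signature", "normalize_between_datasets",
    "impute_clinical",
]


def read_expression(path, sep: str = "\t") -> ExpressionMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: expression table has no sample columns")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = df.columns[df.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
        raise ValueError(
            f"{path}: non-numeric expression cells in column(s) {list(bad)[:5]}"
        ) from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    expr.data.to_csv(path, sep=sep, index_label="gene_id")


def read_clinical(path, sep: str = "\t"):
    """Read the clinical table -> (SurvivalOutcome, ClinicalTable)."""
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""],
                     float_precision="round_trip")
    required = ["sample_id", "time_days", "event", "age", "fab", "eln2017"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id rows {dup[:5]}")
    if df["time_days"].isna().any() or df["event"].isna().any():
        rows = df.index[df["time_days"].isna() | df["event"].isna()].tolist()
        raise ValueError(f"{path}: missing survival entries at rows {rows[:5]}")
    outcome = SurvivalOutcome(
        df["sample_id"].astype(str).tolist(),
        df["time_days"].to_numpy(float),
        df["event"].to_numpy(),
    )
    clin = df.set_index(df["sample_id"].astype(str))[["age", "fab", "eln2017"]]
    return outcome, ClinicalTable(clin)


def write_clinical(outcome: SurvivalOutcome, clinical: ClinicalTable, path,
                   sep: str = "\t") -> None:
    clin = clinical.align(outcome.sample_ids).data
    df = pd.DataFrame(
        {
            "sample_id": outcome.sample_ids,
            "time_days": outcome.time,
            "event": outcome.event,
            "age": clin["age"].to_numpy(),
            "fab": clin["fab"],
            "eln2017": clin["eln2017"].to_numpy(),
        }
    )
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_signature(path, sep: str = "\t", provenance: str = "") -> GeneSignature:
    df = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in df.columns]
    if "gene" not in cols or "coefficient" not in cols:
        raise ValueError(f"{path}: signature file needs 'gene' and 'coefficient' columns")
    df.columns = cols
    return GeneSignature(
        genes=df["gene"].astype(str).tolist(),
        betas=df["coefficient"].to_numpy(float),
        provenance=provenance or str(path),
    )


def write_signature(sig: GeneSignature, path, sep: str = "\t") -> None:
    pd.DataFrame({"gene": sig.genes, "coefficient": sig.betas}).to_csv(
        path, sep=sep, index=False
    )


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Full quantile normalization of columns (limma-style).

    Every column is mapped onto the mean sorted profile; ties receive the
    reference value interpolated at their average rank, so re-application
    is a no-op for tie-free data.
    """
    from scipy.stats import rankdata

    g = values.shape[0]
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    grid = np.arange(1, g + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return out


def normalize_between_datasets(matrices):
    """Harmonize expression distributions across one or more datasets.

    Restricts every matrix to the intersecting gene universe (order taken
    from the first matrix), concatenates all samples, applies full quantile
    normalization so per-sample distributions coincide, and splits back.
    """
    if len(matrices) == 0:
        raise ValueError("at least one expression matrix required")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    genes = [g for g in matrices[0].gene_ids if g in common]
    if not genes:
        raise ValueError("empty gene intersection across datasets")
    blocks = [m.subset_genes(genes) for m in matrices]
    concat = np.concatenate([b.values for b in blocks], axis=1)
    normed = _quantile_normalize(concat)
    out, col = [], 0
    for b in blocks:
        ns = b.n_samples
        out.append(ExpressionMatrix(
            pd.DataFrame(normed[:, col: col + ns], index=genes,
                         columns=b.sample_ids)
        ))
        col += ns
    return out


def impute_clinical(table: ClinicalTable, rng_seed: int = 0, *,
                    max_iter: int = 10, tol: float = 1e-3,
                    n_estimators: int = 100) -> ClinicalTable:
    """Random-forest imputation of missing clinical covariates.

    missForest-style round-robin: columns initialized by mean/mode, then each
    incomplete column in turn is regressed (RandomForestRegressor for age,
    RandomForestClassifier for FAB / ELN2017) on the remaining columns and
    its missing cells re-predicted, until the relative change drops below
    ``tol`` or ``max_iter`` sweeps. Observed cells are never altered and the
    result is deterministic under a fixed seed.
    """
    df = table.data.copy()
    na = df.isna()
    if not na.to_numpy().any():
        return ClinicalTable(df)
    fully_missing = [c for c in df.columns if na[c].all()]
    if fully_missing:
        raise ValueError(f"column(s) with no observed values: {fully_missing}")

    work = pd.DataFrame(index=df.index)
    work["age"] = df["age"].astype(float)
    work["fab"] = df["fab"].astype("Float64").astype(float)
    eln_codes = pd.Categorical(df["eln2017"],
                               categories=["Favorable", "Intermediate", "Adverse"])
    work["eln2017"] = np.where(df["eln2017"].isna(), np.nan,
                               eln_codes.codes.astype(float))
    numeric = {"age"}
    # initial fill: mean / mode
    for c in work.columns:
        obs = work[c][~na[c].to_numpy()]
        fill = obs.mean() if c in numeric else obs.mode().iloc[0]
        work.loc[na[c].to_numpy(), c] = fill

    # least-missing columns first (missForest convention)
    cols = sorted([c for c in work.columns if na[c].any()],
                  key=lambda c: na[c].sum())
    for sweep in range(max_iter):
        max_change = 0.0
        for c in cols:
            miss = na[c].to_numpy()
            Xcols = [x for x in work.columns if x != c]
            X = work[Xcols].to_numpy(float)
            y = work[c].to_numpy(float)
            if c in numeric:
                model = RandomForestRegressor(
                    n_estimators=n_estimators, random_state=rng_seed, n_jobs=1
                )
                model.fit(X[~miss], y[~miss])
                pred = model.predict(X[miss])
                denom = np.sqrt(np.mean(y[miss] ** 2)) or 1.0
                change = np.sqrt(np.mean((pred - y[miss]) ** 2)) / denom
            else:
                model = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=rng_seed, n_jobs=1
                )
                model.fit(X[~miss], y[~miss].astype(int))
                pred = model.predict(X[miss]).astype(float)
                change = float(np.mean(pred != y[miss]))
            work.loc[miss, c] = pred
            max_change = max(max_change, change)
        if max_change < tol:
            break

    out = df.copy()
    out["age"] = np.where(na["age"], work["age"], df["age"])
    fab_filled = np.rint(work["fab"].to_numpy(float)).clip(0, 7).astype(int)
    out["fab"] = np.where(na["fab"], fab_filled, work["fab"].to_numpy(float)).astype(int)
    eln_names = np.array(["Favorable", "Intermediate", "Adverse"])
    eln_filled = eln_names[np.rint(work["eln2017"].to_numpy(float)).clip(0, 2).astype(int)]
    out["eln2017"] = np.where(na["eln2017"], eln_filled, df["eln2017"])
    return ClinicalTable(out)
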