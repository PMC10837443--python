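"""Core data containers shared across the pipeline.

All containers are thin, validated wrappers around pandas/numpy objects:
an :class:`ExpressionMatrix` (genes x samples, log2 scale), a right-censored
:class:`SurvivalOutcome`, a :class:`ClinicalTable` of covariates with explicit
missingness, and a :class:`GeneSignature` mapping expression to a scalar
linear predictor via fixed Cox coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FAB_LEVELS = tuple(range(8))
ELN_LEVELS = ("Favorable", "Intermediate", "Adverse")


@dataclass
class ExpressionMatrix:
    """Log-scale gene x sample abundance table.

    Parameters
    ----------
    data
        DataFrame indexed by gene identifier with one column per sample.
        All values must be finite; gene and sample identifiers unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from expression matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(sample_ids)])


@dataclass
class SurvivalOutcome:
    """Right-censored overall survival: time in days, event 1=dead 0=censored."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if not (len(self.sample_ids) == self.time.size == self.event.size):
            raise ValueError("sample_ids, time and event must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers in outcome")
        if not np.isfinite(self.time).all() or (self.time <= 0).any():
            raise ValueError("survival times must be finite and strictly positive")
        if not np.isin(self.event, [0, 1]).all():
            bad = np.unique(self.event[~np.isin(self.event, [0, 1])])
            raise ValueError(f"event indicator must be 0/1, found {bad.tolist()}")
        self.event = self.event.astype(int)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalOutcome":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SurvivalOutcome(
            [self.sample_ids[i] for i in idx], self.time[idx], self.event[idx]
        )

    def align(self, sample_ids) -> "SurvivalOutcome":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from outcome: {missing[:5]}")
        return self.subset([pos[s] for s in sample_ids])

    def to_structured(self) -> np.ndarray:
        """scikit-survival style structured array (event, time)."""
        return np.array(
            list(zip(self.event.astype(bool), self.time)),
            dtype=[("event", "?"), ("time", "<f8")],
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates: age (years), FAB 0-7, ELN2017 group.

    Missing entries are pd.NA / NaN; categories outside the declared domains
    are rejected at construction.
    """

    data: pd.DataFrame  # index sample_id; columns age, fab, eln2017

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = ["age", "fab", "eln2017"]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise ValueError(f"clinical table lacks columns {missing_cols}")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in clinical table")
        df["age"] = pd.to_numeric(df["age"], errors="raise")
        fab = pd.to_numeric(df["fab"], errors="raise")
        ok = fab.isna() | fab.isin(FAB_LEVELS)
        if not ok.all():
            raise ValueError(
                f"FAB categories outside 0-7: {fab[~ok].unique().tolist()}"
            )
        df["fab"] = fab.astype("Int64")
        eln = df["eln2017"]
        ok = eln.isna() | eln.isin(ELN_LEVELS)
        if not ok.all():
            raise ValueError(
                f"ELN2017 categories outside {ELN_LEVELS}: {eln[~ok].unique().tolist()}"
            )
        self.data = df[required]

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def align(self, sample_ids) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:5]}")
        return ClinicalTable(self.data.loc[list(sample_ids)])


@dataclass
class GeneSignature:
    """Ordered gene list with Cox coefficients; risk score = sum(beta_i * Exp_i)."""

    genes: list
    betas: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.genes) != self.betas.size:
            raise ValueError("genes and betas must align")
        if len(self.genes) == 0:
            raise ValueError("a signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if (self.betas == 0).any():
            raise ValueError("zero coefficients must not be retained in a signature")
        if not np.isfinite(self.betas).all():
            raise ValueError("non-finite signature coefficient")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.betas, index=self.genes, name="coefficient")


@dataclass
class RiskScoreVector:
    """Per-sample linear predictor of a gene signature."""

    sample_ids: list
    score: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.score = np.asarray(self.score, dtype=float)
        if len(self.sample_ids) != self.score.size:
            raise ValueError("sample_ids and score must align")

    def as_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.sample_ids, name="risk_score")


@dataclass
class GroundTruth:
    """Known generating model of a simulated cohort."""

    causal_genes: list
    true_beta: dict
    true_lp: pd.Series  # indexed by sample id
    submodel_informativeness: dict = field(default_factory=dict)
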