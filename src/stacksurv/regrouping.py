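"""Merge ELN2017 genetic-risk groups with the model's dichotomized risk.

The 3x2 grid (ELN group x model low/high) collapses onto three new risk
groups. The default reading assigns every model-high subgroup to high risk
("the remaining three subgroups"): (Favorable, low) -> low;
(Intermediate, low), (Adverse, low) -> intermediate; all (*, high) -> high.
An alternative reading that keeps (Favorable, high) in the low-risk group
is available via ``favorable_high_to``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import bonferroni_adjust, logrank_test
from .types import ELN_LEVELS, SurvivalOutcome

__all__ = ["RiskGroupLabels", "merge_eln_model", "group_separation"]

MERGED_LEVELS = ("low", "intermediate", "high")
MODEL_LEVELS = ("low", "high")


@dataclass
class RiskGroupLabels:
    sample_ids: list
    eln: np.ndarray
    model_risk: np.ndarray
    merged: np.ndarray


def merge_eln_model(eln_labels, model_risk_labels, sample_ids=None, *,
                    favorable_high_to: str = "high") -> RiskGroupLabels:
    """Deterministic (ELN2017, model risk) -> {low, intermediate, high} map.

    ``favorable_high_to`` selects the reading for the (Favorable, high)
    cell: "high" (default; yields exactly three high subgroups) or "low".
    """
    eln = np.asarray(eln_labels, dtype=object)
    model = np.asarray(model_risk_labels, dtype=object)
    if eln.size != model.size:
        raise ValueError("ELN and model-risk labels must align")
    bad = set(np.unique(eln)) - set(ELN_LEVELS)
    if bad:
        raise ValueError(f"unknown ELN2017 categor{'y' if len(bad)==1 else 'ies'}: "
                         f"{sorted(bad)}")
    bad = set(np.unique(model)) - set(MODEL_LEVELS)
    if bad:
        raise ValueError(f"unknown model risk label(s): {sorted(bad)}")
    if favorable_high_to not in ("high", "low"):
        raise ValueError("favorable_high_to must be 'high' or 'low'")
    mapping = {
        ("Favorable", "low"): "low",
        ("Intermediate", "low"): "intermediate",
        ("Adverse", "low"): "intermediate",
        ("Favorable", "high"): favorable_high_to,
        ("Intermediate", "high"): "high",
        ("Adverse", "high"): "high",
    }
    merged = np.array([mapping[(e, m)] for e, m in zip(eln, model)], dtype=object)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(eln.size)]
    return RiskGroupLabels(list(sample_ids), eln, model, merged)


def group_separation(labels: RiskGroupLabels, outcome: SurvivalOutcome):
    """Overall and pairwise log-rank separation of the merged risk groups.

    Returns ``(overall_p, pairwise_table)`` where the table has one row per
    group pair with chi2, raw p, and the Bonferroni decision at m = 3
    comparisons (threshold 0.05/3 ~ 0.017).
    """
    merged = np.asarray(labels.merged, dtype=object)
    present = [g for g in MERGED_LEVELS if (merged == g).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty merged groups")
    chi2, df, overall_p = logrank_test(merged, outcome)
    rows = []
    pairs = [(a, b) for i, a in enumerate(MERGED_LEVELS)
             for b in MERGED_LEVELS[i + 1:]]
    for a, b in pairs:
        mask = (merged == a) | (merged == b)
        if not (merged == a).any() or not (merged == b).any():
            rows.append({"group_a": a, "group_b": b, "chi2": np.nan,
                         "p": np.nan, "note": "empty group; skipped"})
            continue
        sub = outcome.subset(mask)
        c2, _, p = logrank_test(merged[mask], sub)
        rows.append({"group_a": a, "group_b": b, "chi2": c2, "p": p, "note": ""})
    table = pd.DataFrame(rows)
    valid = table["p"].notna()
    decisions = np.full(len(table), False)
    if valid.any():
        decisions[valid.to_numpy()] = bonferroni_adjust(
            table.loc[valid, "p"].to_numpy(), m=3
        ).significant
    table["bonferroni_significant"] = decisions
    return float(overall_p), table
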