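"""Minimal matplotlib helpers for the evaluation outputs.

Each helper draws onto a provided or fresh Axes and returns it; curve
coordinates are available from the corresponding result objects for TSV
export.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np


def plot_td_roc(curves, ax=None):
    """Overlay one or more TdRocCurve objects."""
    if ax is None:
        _, ax = plt.subplots()
    for c in np.atleast_1d(curves):
        ax.plot(c.fpr, c.tpr,
                label=f"t={c.eval_time:g} d (AUC={c.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    return ax

def plot_km(curve, ax=None, label=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.step(np.r_[0, curve.times], np.r_[1.0, curve.survival], where="post",
            label=label)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    if label:
        ax.legend()
    return ax


def plot_calibration(table, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table.table["predicted"], table.table["observed"], "o-")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel(f"predicted survival at t={table.eval_time:g} d")
    ax.set_ylabel("observed (KM) survival")
    return ax
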