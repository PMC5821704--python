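"""Calibration and ROC figures."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

# deterministic SVG output (stable element ids, no embedded date)
matplotlib.rcParams["svg.hashsalt"] = "tkrsat"


def plot_calibration(calibration, ax=None, title="Calibration"):
    """Observed event proportion vs mean predicted risk per decile.

    Vertical bars are the 95% Agresti-Coull intervals of the observed
    proportions; the diagonal marks perfect calibration.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    x = calibration["mean_predicted"]
    y = calibration["observed"]
    yerr = np.vstack([y - calibration["ci_low"], calibration["ci_high"] - y])
    ax.errorbar(x, y, yerr=yerr, fmt="o", capsize=3, color="tab:blue")
    lim = max(0.05, float(calibration["ci_high"].max()), float(x.max())) * 1.05
    ax.plot([0, lim], [0, lim], "--", color="grey", lw=1)
    ax.set_xlabel("Mean predicted probability of non-satisfaction")
    ax.set_ylabel("Observed proportion non-satisfied")
    ax.set_title(title)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    return ax


def plot_roc(probabilities, outcomes, ax=None, label=None):
    """Empirical ROC curve (sensitivity vs 1-specificity over thresholds)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    order = np.argsort(-p, kind="stable")
    y = y[order]
    tpr = np.concatenate([[0], np.cumsum(y) / y.sum()])
    fpr = np.concatenate([[0], np.cumsum(1 - y) / (1 - y).sum()])
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    if label:
        ax.legend()
    return ax


def save(fig_or_ax, path):
    fig = getattr(fig_or_ax, "figure", fig_or_ax)
    kwargs = {}
    if str(path).endswith(".svg"):
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, bbox_inches="tight", **kwargs)
    plt.close(fig)
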