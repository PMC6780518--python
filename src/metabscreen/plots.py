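"""Diagnostic plots: stability-selection ROC bundles and RF error-vs-trees curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pls import StabilitySelectionResult
from .rf import RFEvaluationResult, error_curve_summary

__all__ = ["plot_roc_bundle", "plot_error_curves"]


def plot_roc_bundle(result: StabilitySelectionResult, path: str | Path) -> None:
    """All per-model ROC curves (grey) with 10/50/90 percentile curves (red
    dashed) interpolated on a common false-positive-rate grid."""
    fig, ax = plt.subplots(figsize=(5, 5))
    grid = np.linspace(0, 1, 101)
    tprs = []
    for fpr, tpr in result.roc_curves:
        ax.plot(fpr, tpr, color="0.6", lw=0.5, alpha=0.5)
        tprs.append(np.interp(grid, fpr, tpr))
    if tprs:
        tprs = np.array(tprs)
        for q in (10, 50, 90):
            ax.plot(grid, np.percentile(tprs, q, axis=0), "r--", lw=1.5)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"held-out ROC over {result.n_models} subsample models")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_error_curves(result: RFEvaluationResult, path: str | Path) -> None:
    """Total (black) and per-class (red = control, green = case) held-out
    error versus number of trees, with percentile overlays (dashed)."""
    df = error_curve_summary(result)
    fig, ax = plt.subplots(figsize=(6, 4))
    k = df["n_trees"]
    for name, color in (("control", "red"), ("case", "green"), ("total", "black")):
        ax.plot(k, df[f"{name}_p50"], color=color, lw=1.2, label=f"{name} (median)")
        for q in (10, 90):
            ax.plot(k, df[f"{name}_p{q}"], color=color, lw=0.8, ls="--", alpha=0.6)
    ax.set_xlabel("number of trees")
    ax.set_ylabel("held-out error")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
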