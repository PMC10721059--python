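"""Diagnostic plots: per-test confidence-interval panels and realization-weight plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["ci_panel", "weight_plot"]


def ci_panel(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    beta_true: float,
    labels: tuple[str, str] = ("CIM", "FMA"),
    max_tests: int = 100,
    sort_by_a: bool = True,
):
    """Side-by-side per-test interval panels for two methods.

    Tests are ordered by method A's point estimate; intervals missing the
    true slope are drawn in red.  Returns the matplotlib figure.
    """
    a = records_a.set_index("test")
    b = records_b.set_index("test").loc[a.index]
    if len(a) > max_tests:
        a = a.iloc[:max_tests]
        b = b.loc[a.index]
    if sort_by_a:
        order = a["beta_hat"].sort_values().index
        a, b = a.loc[order], b.loc[order]

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, rec, label in zip(axes, (a, b), labels):
        x = np.arange(len(rec))
        miss = (rec["ci_low"] > beta_true) | (rec["ci_high"] < beta_true)
        for xi, (lo, hi, m) in enumerate(zip(rec["ci_low"], rec["ci_high"], miss)):
            ax.plot([xi, xi], [lo, hi], color="red" if m else "0.6", lw=0.8)
        ax.plot(x, rec["beta_hat"], ".", ms=2, color="black")
        ax.axhline(beta_true, ls="--", color="blue", lw=0.8)
        ax.set_title(label)
        ax.set_xlabel("test (sorted)")
    axes[0].set_ylabel("slope estimate and 95% interval")
    fig.tight_layout()
    return fig


def weight_plot(weights: np.ndarray, label: str = "FW", top_annotate: int = 3):
    """Stem plot of per-realization averaging weights for one test."""
    weights = np.asarray(weights, dtype=float)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.vlines(np.arange(weights.size), 0.0, weights, color="0.4", lw=0.7)
    top = np.argsort(weights)[::-1][:top_annotate]
    for k in top:
        if weights[k] > 0:
            ax.annotate(f"k={k}", (k, weights[k]), fontsize=7, ha="center",
                        xytext=(0, 3), textcoords="offset points")
    ax.set_xlabel("dose realization index")
    ax.set_ylabel(f"{label} weight")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    return fig
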