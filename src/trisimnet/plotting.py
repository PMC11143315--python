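"""Accuracy-vs-threshold plots for sensitivity sweeps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_accuracy_vs_threshold"]


def plot_accuracy_vs_threshold(table: pd.DataFrame, path: str | Path) -> None:
    """One panel per metric: test accuracy against the edge threshold,
    with the tabular baselines drawn as horizontal comparison lines."""
    metrics = [m for m in table["metric"].unique() if m != "tabular"]
    baselines = table[table["metric"] == "tabular"]
    fig, axes = plt.subplots(
        1, max(len(metrics), 1), figsize=(4 * max(len(metrics), 1), 3.2), squeeze=False
    )
    for ax, metric in zip(axes[0], metrics):
        sub = table[table["metric"] == metric]
        for model, grp in sub.groupby("model"):
            grp = grp.sort_values("threshold")
            ax.plot(grp["threshold"], grp["test_accuracy"], marker="o", label=model)
        for _, row in baselines.iterrows():
            ax.axhline(row["test_accuracy"], linestyle="--", linewidth=1, alpha=0.7)
        ax.set_title(metric)
        ax.set_xlabel("threshold")
        ax.set_ylabel("test accuracy")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
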