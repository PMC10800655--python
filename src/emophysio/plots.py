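"""Figure helpers: class-box overlap plots and benchmark bar charts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .square import class_boxes

QUADRANT_COLORS = {
    "A1_LV": "tab:blue", "A1_HV": "tab:green",
    "A4_LV": "tab:red", "A4_HV": "tab:orange",
}


def plot_class_boxes(table: pd.DataFrame, pair: tuple[str, str], ax=None,
                     class_col: str = "quadrant"):
    """Draw the per-class 95%-CI rectangles for one feature pair."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for box in class_boxes(table, pair, class_col):
        x0, x1, y0, y1 = box.bounds
        color = QUADRANT_COLORS.get(box.class_label, "gray")
        ax.add_patch(plt.Rectangle((x0, y0), x1 - x0, y1 - y0, fill=False,
                                   edgecolor=color, linewidth=1.5,
                                   label=box.class_label))
        ax.plot(*box.center, "*", color=color)
    ax.set_xlabel(pair[0])
    ax.set_ylabel(pair[1])
    ax.relim()
    ax.autoscale_view()
    ax.legend(fontsize=8)
    return ax


def plot_benchmark(records: pd.DataFrame, condition: str, ax=None):
    """Bar chart of best-model validation accuracy per overlap threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = records[records["condition"] == condition]
    idx = sub.groupby("threshold")["mean_accuracy"].idxmax()
    best = sub.loc[idx].sort_values("threshold", ascending=False)
    xs = [f"{t:g}%" for t in best["threshold"]]
    ax.bar(xs, best["mean_accuracy"], yerr=best["sd_accuracy"], color="tab:blue")
    for x, (_, row) in zip(xs, best.iterrows()):
        ax.annotate(f"{row['model']}\n{row['n_features']}f",
                    (x, row["mean_accuracy"] / 2), ha="center", fontsize=8)
    ax.axhline(0.25, ls="--", color="gray", lw=1)  # 4-class chance
    ax.set_xlabel("overlap threshold")
    ax.set_ylabel("validation accuracy")
    ax.set_title(condition)
    return ax
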