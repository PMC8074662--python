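"""Basic plots: LI summary by task/group, test-retest scatter, factor-score
scatter with covariance ellipses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scores import covariance_ellipse
from .types import TASKS, LITable


def plot_li_summary(table: LITable, path=None):
    """Per-task/session LI distributions for each group (jittered points,
    group mean bars)."""
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    rng = np.random.default_rng(0)
    for ax, group in zip(axes, ("left", "right")):
        vals = table.group_values(group)
        for i, ind in enumerate(vals.columns):
            x = vals[ind].dropna().to_numpy()
            ax.scatter(np.full(len(x), i) + rng.uniform(-0.15, 0.15, len(x)), x,
                       s=8, alpha=0.5)
            if len(x):
                ax.hlines(x.mean(), i - 0.3, i + 0.3, color="k")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xticks(range(len(vals.columns)))
        ax.set_xticklabels(vals.columns, rotation=90, fontsize=7)
        ax.set_title(f"{group}-handers (n={len(vals)})")
    axes[0].set_ylabel("LI (%)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_test_retest(table: LITable, path=None):
    """Session-1 vs session-2 scatter per task, colour-coded by group."""
    fig, axes = plt.subplots(2, 3, figsize=(10, 6))
    colors = {"left": "tab:red", "right": "tab:blue"}
    for ax, t in zip(axes.ravel(), TASKS):
        for group in table.groups.unique():
            sub = table.group_values(group)[[f"{t}1", f"{t}2"]].dropna()
            ax.scatter(sub[f"{t}1"], sub[f"{t}2"], s=10, alpha=0.6,
                       color=colors.get(group, "k"), label=group)
        lims = ax.get_xlim()
        ax.plot(lims, lims, color="grey", lw=0.5)
        ax.set_title(f"task {t}", fontsize=9)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_factor_scores(scores: pd.DataFrame, outliers=None, path=None):
    """Factor-1 vs factor-2 weighted LI means with per-group 95% covariance
    ellipses; flagged outliers drawn filled."""
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {"left": "tab:red", "right": "k"}
    theta = np.linspace(0, 2 * np.pi, 200)
    for group, sub in scores.groupby("group"):
        pts = sub[["factor1", "factor2"]].dropna()
        c = colors.get(group, "tab:green")
        filled = outliers.reindex(pts.index).fillna(False) if outliers is not None else None
        face = ["none" if (filled is None or not filled.loc[i]) else c for i in pts.index]
        ax.scatter(pts["factor1"], pts["factor2"], edgecolors=c, facecolors=face, label=group)
        if len(pts) >= 3:
            ell = covariance_ellipse(pts.to_numpy(float))
            a, b = ell["semi_axes"]
            ang = ell["angle_rad"]
            xs = a * np.cos(theta)
            ys = b * np.sin(theta)
            ax.plot(
                ell["center"][0] + xs * np.cos(ang) - ys * np.sin(ang),
                ell["center"][1] + xs * np.sin(ang) + ys * np.cos(ang),
                color=c, lw=1,
            )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("weighted LI mean, factor 1")
    ax.set_ylabel("weighted LI mean, factor 2")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
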