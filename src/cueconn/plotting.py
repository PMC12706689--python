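"""Connectivity visualization: heatmaps, montage network maps, region graphs.

Plots are artifacts, produced on demand (the ``report`` CLI subcommand or
direct calls), never side effects of the analysis.  All functions return
the matplotlib Figure so callers control saving and closing.
"""

from __future__ import annotations

import numpy as np

from .group import DifferenceMatrix, GroupSummary, extract_network
from .montage import Montage

__all__ = ["plot_heatmap", "plot_difference", "plot_network", "plot_region_table"]


def _fig(figsize):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def plot_heatmap(summary: GroupSummary, annotate_robust: bool = True):
    """Group-mean F heatmap; robust connections are starred."""
    fig, ax = _fig((9, 8))
    labs = summary.channel_labels
    im = ax.imshow(summary.mean_F, cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="mean F")
    ax.set_xticks(range(len(labs)), labs, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labs)), labs, fontsize=6)
    ax.set_xlabel("source")
    ax.set_ylabel("target")
    ax.set_title(f"Directed connectivity ({summary.condition}); "
                 f"threshold {summary.viz_threshold:.2f}")
    if annotate_robust:
        t_idx, s_idx = np.nonzero(summary.robust_mask)
        for t, s in zip(t_idx, s_idx):
            ax.text(s, t, "*", ha="center", va="center", fontsize=5)
    return fig


def plot_difference(diff: DifferenceMatrix):
    """Color-minus-lexical difference heatmap with C/L/* markers."""
    fig, ax = _fig((9, 8))
    labs = diff.channel_labels
    vmax = np.nanmax(np.abs(diff.diff_F))
    im = ax.imshow(diff.diff_F, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax, label="color - lexical mean F")
    ax.set_xticks(range(len(labs)), labs, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labs)), labs, fontsize=6)
    ax.set_xlabel("source")
    ax.set_ylabel("target")
    marks = diff.markers_combined()
    for t in range(len(labs)):
        for s in range(len(labs)):
            if s != t and marks[t, s]:
                ax.text(s, t, marks[t, s], ha="center", va="center", fontsize=5)
    ax.set_title("Condition difference map")
    return fig


_REGION_COLORS = {
    "frontal": "#d62728", "central": "#17becf", "left_temporal": "#c5b0d5",
    "right_temporal": "#6a3d9a", "parietal": "#2ca02c", "occipital": "#ffd700",
}


def plot_network(summary: GroupSummary, montage: Montage,
                 threshold="mean_plus_sd"):
    """Supra-threshold connections drawn on the 2-D montage."""
    fig, ax = _fig((8, 8))
    edges = extract_network(summary, threshold)
    pos = montage.positions
    for lab in summary.channel_labels:
        x, y = pos[lab]
        region = montage.regions.get(lab, "")
        ax.scatter(x, y, s=220, color=_REGION_COLORS.get(region, "#999999"),
                   zorder=3, edgecolors="white")
        ax.annotate(lab, (x, y), ha="center", va="center", fontsize=6, zorder=4)
    if not edges.empty:
        fmax = edges["F"].max()
        for _, e in edges.iterrows():
            x0, y0 = pos[e.source]
            x1, y1 = pos[e.target]
            ax.annotate(
                "", xy=(x1, y1), xytext=(x0, y0),
                arrowprops=dict(arrowstyle="-|>", lw=0.5 + 2.5 * e.F / fmax,
                                color="0.3", alpha=0.7),
            )
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"Supra-threshold network ({summary.condition})")
    return fig


def plot_region_table(table, title: str = "Region-level connectivity"):
    """Ordered region x region aggregate as an annotated heatmap."""
    fig, ax = _fig((6, 5))
    vals = np.asarray(table, dtype=float)
    im = ax.imshow(vals, cmap="viridis")
    fig.colorbar(im, ax=ax)
    ax.set_xticks(range(len(table.columns)), table.columns, rotation=45,
                  ha="right", fontsize=8)
    ax.set_yticks(range(len(table.index)), table.index, fontsize=8)
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            ax.text(j, i, f"{vals[i, j]:g}", ha="center", va="center",
                    fontsize=7, color="white")
    ax.set_xlabel("target region")
    ax.set_ylabel("source region")
    ax.set_title(title)
    fig.tight_layout()
    return fig
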