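"""Figure rendering for the pipeline outputs (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .evolution import ClusterResult, expected_enc_curve


def _save(fig, out_base: Path) -> list:
    paths = []
    for ext in ("png", "svg"):
        p = out_base.with_suffix(f".{ext}")
        fig.savefig(p, bbox_inches="tight", dpi=150)
        paths.append(p)
    plt.close(fig)
    return paths


def _family_colors(families):
    cmap = plt.get_cmap("tab20")
    uniq = sorted(pd.unique(families))
    return {f: cmap(i % 20) for i, f in enumerate(uniq)}, uniq


def plot_enc_gc3s(points: pd.DataFrame, out_base) -> list:
    """ENC vs GC3s scatter with Wright's expected curve."""
    fig, ax = plt.subplots(figsize=(6, 5))
    grid = np.linspace(0.0, 1.0, 201)
    ax.plot(grid, expected_enc_curve(grid), "k-", lw=1.2,
            label="expected (mutation only)")
    colors, families = _family_colors(points["family"])
    for fam in families:
        sub = points[points["family"] == fam]
        ax.scatter(sub["gc3s"], sub["enc"], s=12, color=colors[fam],
                   label=fam, alpha=0.8)
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 65)
    ax.legend(fontsize=6, ncol=2)
    return _save(fig, Path(out_base))


def plot_pr2(indices: pd.DataFrame, out_base) -> list:
    """PR2 scatter: A3/(A3+U3) vs G3/(G3+C3) with center lines at 0.5."""
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    colors, families = _family_colors(indices["family"])
    for fam in families:
        sub = indices[indices["family"] == fam]
        ax.scatter(sub["gc_bias"], sub["au_bias"], s=12, color=colors[fam],
                   label=fam, alpha=0.8)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + U3)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=6, ncol=2)
    return _save(fig, Path(out_base))


def plot_neutrality(composition: pd.DataFrame, fits: pd.DataFrame,
                    out_base) -> list:
    """GC12 vs GC3 scatter with per-family regression lines."""
    fig, ax = plt.subplots(figsize=(6, 5))
    colors, families = _family_colors(composition["family"])
    for fam in families:
        sub = composition[composition["family"] == fam]
        ax.scatter(sub["gc3"], sub["gc12"], s=12, color=colors[fam],
                   label=fam, alpha=0.8)
        fit = fits[fits["group"] == fam]
        if len(fit) == 1:
            x = np.linspace(sub["gc3"].min(), sub["gc3"].max(), 10)
            ax.plot(x, fit["intercept"].iloc[0] + fit["slope"].iloc[0] * x,
                    color=colors[fam], lw=1.0)
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(fontsize=6, ncol=2)
    return _save(fig, Path(out_base))


def plot_rscu_heatmap(cluster: ClusterResult, out_base) -> list:
    """Clustered RSCU heatmap with marginal dendrograms."""
    m = cluster.matrix
    fig = plt.figure(figsize=(max(8, 0.16 * m.shape[1]), 4 + 0.25 * m.shape[0]))
    gs = fig.add_gridspec(2, 2, width_ratios=(1, 6), height_ratios=(1, 4),
                          wspace=0.02, hspace=0.02)
    ax_col = fig.add_subplot(gs[0, 1])
    hierarchy.dendrogram(cluster.col_linkage, ax=ax_col, no_labels=True,
                         color_threshold=0, link_color_func=lambda _: "k")
    ax_col.axis("off")
    ax_row = fig.add_subplot(gs[1, 0])
    hierarchy.dendrogram(cluster.row_linkage, ax=ax_row, orientation="left",
                         no_labels=True, color_threshold=0,
                         link_color_func=lambda _: "k")
    ax_row.axis("off")
    ax = fig.add_subplot(gs[1, 1])
    # dendrogram plots leaves bottom-to-top in 'left' orientation
    im = ax.pcolormesh(m.to_numpy()[::-1], cmap="RdBu_r")
    ax.set_xticks(np.arange(m.shape[1]) + 0.5)
    ax.set_xticklabels(m.columns, rotation=90, fontsize=5)
    ax.set_yticks(np.arange(m.shape[0]) + 0.5)
    ax.set_yticklabels(m.index[::-1], fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.6, label="RSCU")
    return _save(fig, Path(out_base))
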