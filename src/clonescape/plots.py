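"""Plot exports: per-site diversity bubble maps and connectivity heatmaps."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def site_bubble_map(
    stats: pd.DataFrame,
    coords: pd.DataFrame | None = None,
    path=None,
):
    """Bubble panels of per-site R, F_IS and r̄_d.

    ``stats`` is the :func:`clonescape.divstats.site_stats` table;
    ``coords`` optionally supplies columns (site, x, y) for a map-like
    layout, otherwise sites are spread on a line.  Bubble area tracks
    the magnitude of each statistic (each panel on its own scale).
    """
    if coords is not None:
        merged = stats.merge(coords, on="site", how="left")
        x, y = merged["x"].to_numpy(), merged["y"].to_numpy()
    else:
        x = np.arange(len(stats), dtype=float)
        y = np.zeros(len(stats))
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharex=True, sharey=True)
    for ax, col, title in zip(
        axes, ["R", "fis", "r_bar_d"], ["clonal richness R", "F_IS", "r̄_d"]
    ):
        v = stats[col].to_numpy(dtype=float)
        size = 40 + 260 * (np.abs(v) / max(np.nanmax(np.abs(v)), 1e-9))
        sc = ax.scatter(x, y, s=size, c=v, cmap="viridis", edgecolor="k", lw=0.4)
        for xi, yi, s in zip(x, y, stats["site"]):
            ax.annotate(str(s), (xi, yi), fontsize=6, ha="center", va="bottom")
        fig.colorbar(sc, ax=ax, shrink=0.8)
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def connectivity_heatmap(result, path=None, log: bool = True):
    """Heatmap of multi-generation connectivity.

    Follows the source-in-columns / destination-in-rows orientation of
    seascape connectivity matrices.
    """
    M = result.heatmap_array()
    fig, ax = plt.subplots(figsize=(6, 5))
    disp = np.log10(M + 1e-12) if log else M
    im = ax.imshow(disp, cmap="magma", origin="upper")
    ax.set_xlabel("source site (column)")
    ax.set_ylabel("destination site (row)")
    ax.set_xticks(range(len(result.site_labels)))
    ax.set_xticklabels(result.site_labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(result.site_labels)))
    ax.set_yticklabels(result.site_labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="log10 probability" if log else "probability")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
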