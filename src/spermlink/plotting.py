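"""Plots: physical-vs-genetic map correspondence and the cell-count curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_map(results, path=None):
    """Physical (scaffold bp) vs genetic (cM) positions per linkage group.

    Oriented contigs are drawn dark, unoriented ones light; flat runs of
    identical cM mark regions (typically centromeric) where no
    recombination was observed.
    """
    df = results.map_table()
    groups = results.map.groups
    n = max(len(groups), 1)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 4), squeeze=False)
    for ax, gname in zip(axes[0], groups):
        sub = df[df["group"] == gname].sort_values("order_index")
        for _, row in sub.iterrows():
            color = "0.2" if row["orientation"] != "?" else "0.75"
            ax.plot(
                [row["phys_start"], row["phys_end"]],
                [row["cM_start"], row["cM_end"]],
                color=color,
                lw=2,
            )
        ax.set_title(gname)
        ax.set_xlabel("physical (bp)")
    axes[0][0].set_ylabel("genetic (cM)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_cell_count_curve(summary, path=None):
    """Oriented-base percentage vs number of cells (log2 x-axis)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        summary["n_cells"],
        summary["oriented_mean"],
        yerr=summary["oriented_sd"].fillna(0.0),
        marker="o",
        capsize=3,
    )
    ax.set_xscale("log", base=2)
    ax.set_xlabel("number of cells")
    ax.set_ylabel("oriented bases (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
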