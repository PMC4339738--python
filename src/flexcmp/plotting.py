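"""Optional matplotlib output (heat maps with dendrograms, profiles).

matplotlib is imported lazily so the core package runs headless without
a plotting stack.
"""
from __future__ import annotations

import numpy as np


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_similarity_heatmap(sim, path) -> None:
    """Heat map of a similarity matrix with its complete-linkage
    dendrogram on the top edge; rows/columns keep input order."""
    from scipy.cluster.hierarchy import dendrogram

    plt = _mpl()
    k = len(sim.labels)
    fig, (ax_dend, ax_heat) = plt.subplots(
        2, 1, figsize=(max(5, 0.5 * k), max(6, 0.6 * k)),
        gridspec_kw={"height_ratios": [1, 4]},
    )
    dendrogram(sim.linkage_matrix, labels=sim.labels, ax=ax_dend,
               color_threshold=0.0)
    ax_dend.set_ylabel(f"1 - {sim.measure}")
    im = ax_heat.imshow(sim.values, vmin=np.nanmin(sim.values), vmax=1.0,
                        cmap="viridis")
    ax_heat.set_xticks(range(k), sim.labels, rotation=90, fontsize=7)
    ax_heat.set_yticks(range(k), sim.labels, fontsize=7)
    fig.colorbar(im, ax=ax_heat, label=sim.measure)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)


def plot_profiles(table, path) -> None:
    """Aligned profiles, one line per structure, gaps left blank."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(8, 4))
    for col in table.data.columns:
        ax.plot(table.data.index, table.data[col], label=str(col), lw=1)
    ax.set_xlabel("alignment column")
    ax.set_ylabel(f"normalised {table.kind}")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)


def plot_overlap(result, path) -> None:
    """Squared and cumulative overlap against mode number."""
    plt = _mpl()
    modes = np.arange(1, result.squared_overlaps.size + 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(modes, result.squared_overlaps, label="squared overlap")
    ax.plot(modes, result.cumulative, color="crimson", label="cumulative")
    ax.set_xlabel("mode number (non-trivial)")
    ax.set_ylabel("overlap")
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
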