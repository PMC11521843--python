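"""Rendering: motif stacked-bar plots and disparity-graph images.

The data products (motif tables, graphs) are serialized first; these
functions are a thin matplotlib layer over them, so nothing downstream
depends on pixels.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx

from .atlas import MotifTable

# 20 distinguishable colours keyed by residue letter, gaps in light grey
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CMAP = plt.get_cmap("tab20")
RESIDUE_COLOURS = {r: _CMAP(i % 20) for i, r in enumerate(_RESIDUES)}


def plot_motif(table: MotifTable, path, *, title: str = "") -> None:
    """Stacked bars of per-position residue prevalence.

    Bar heights are fractions of alleles; positions covered by no allele in
    the set still get an (empty) slot so monomorphic/uncovered positions
    remain visible.  Output format follows the file extension (png/svg/pdf).
    """
    positions = table.positions
    fig, ax = plt.subplots(figsize=(max(6.0, 0.3 * len(positions)), 3.2))
    x = range(len(positions))
    bottom = [0.0] * len(positions)
    for r in _RESIDUES:
        heights = [table.prevalence.get((p, r), 0.0) for p in positions]
        if not any(heights):
            continue
        ax.bar(x, heights, bottom=bottom, width=0.8, color=RESIDUE_COLOURS[r], label=r)
        bottom = [b + h for b, h in zip(bottom, heights)]
        for xi, (h, b) in enumerate(zip(heights, bottom)):
            if h > 0.08:
                ax.text(xi, b - h / 2, r, ha="center", va="center", fontsize=6)
    ax.set_xticks(list(x))
    ax.set_xticklabels([str(p) for p in positions], rotation=90, fontsize=6)
    ax.set_ylim(0, 1)
    ax.set_xlabel("mature-protein position")
    ax.set_ylabel("prevalence")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_graph(graph: nx.Graph, path, *, seed: int = 0) -> None:
    """Disparity-graph image: external nodes in a contrasting colour,
    edge labels show the distance and are suppressed on monomorphic edges."""
    pos = nx.spring_layout(graph, seed=seed)
    colours = [
        "#d95f02" if graph.nodes[n].get("is_external") else "#1b9e77"
        for n in graph.nodes
    ]
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx(graph, pos, ax=ax, node_color=colours, node_size=500, font_size=6)
    labels = {
        (u, v): d["distance"]
        for u, v, d in graph.edges(data=True)
        if not d.get("monomorphic")
    }
    nx.draw_networkx_edge_labels(graph, pos, edge_labels=labels, ax=ax, font_size=6)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
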