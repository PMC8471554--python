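"""Minimal node-map visualization helper.

Draws the nodes of a GC map as a 2-D scatter (squares for SOZ members,
circles otherwise), highlights the top-ranked nodes, and overlays the
largest-magnitude directed edges. Matplotlib is imported lazily so the rest
of the package has no hard plotting dependency.
"""

from __future__ import annotations

import numpy as np

from .gcmap import GCMap
from .ranking import NodeRanking, top_k


def plot_node_map(
    g: GCMap,
    ranking: NodeRanking | None = None,
    *,
    soz: set[str] | None = None,
    highlight_top: int = 8,
    n_edges: int = 20,
    coords: dict[str, tuple[float, float]] | None = None,
    ax=None,
    layout_seed: int = 0,
):
    """Scatter the nodes of ``g``; returns the matplotlib Axes.

    ``coords`` maps labels to (x, y) positions (e.g. electrode grid
    coordinates); without it a spring layout is computed. The
    ``highlight_top`` best-ranked nodes are coloured, and the ``n_edges``
    heaviest edges drawn as arrows.
    """
    import matplotlib.pyplot as plt

    if coords is None:
        import networkx as nx

        from .ranking import to_networkx

        coords = nx.spring_layout(to_networkx(g), seed=layout_seed)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    soz = soz or set()
    highlighted = top_k(ranking, min(highlight_top, g.n)) if ranking else set()

    for lbl in g.labels:
        x, y = coords[lbl]
        ax.scatter(
            x, y,
            marker="s" if lbl in soz else "o",
            s=120,
            facecolor="gold" if lbl in highlighted else "lightgray",
            edgecolor="black", zorder=3,
        )
        ax.annotate(lbl, (x, y), fontsize=6, ha="center", va="center", zorder=4)

    if n_edges and g.weights.any():
        flat = g.weights.ravel()
        order = np.argsort(flat)[::-1][: min(n_edges, int((flat > 0).sum()))]
        for idx in order:
            i, j = divmod(int(idx), g.n)
            x0, y0 = coords[g.labels[i]]
            x1, y1 = coords[g.labels[j]]
            ax.annotate(
                "", xy=(x1, y1), xytext=(x0, y0),
                arrowprops=dict(arrowstyle="->", color="steelblue", alpha=0.6),
                zorder=2,
            )
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
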