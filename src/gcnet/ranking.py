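"""Deterministic node-importance metrics for GC maps.

Implements weighted PageRank (damped fixed point plus an undamped didactic
mass-transfer update), betweenness and harmonic centrality over inverse-weight
shortest paths, in/outdegree edge counts, and the total-GC-outdegree baseline
(row sum of GC weights). Every metric is wrapped in a :class:`NodeRanking`
whose ranks run 1..N with midranks for ties, rank 1 being the best node in the
algorithm's declared direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._util import midranks
from .gcmap import GCMap, reverse, to_transition

__all__ = [
    "NodeRanking",
    "ConvergenceError",
    "make_ranking",
    "pagerank",
    "pagerank_didactic",
    "betweenness",
    "harmonic",
    "degree_centrality",
    "total_gc_outdegree",
    "top_k",
    "ALGORITHMS",
]


@dataclass
class NodeRanking:
    """Per-node metric values and ranks 1..N (midranks for ties).

    ``higher_is_better`` records the orientation of the metric: visitation
    counts rank descending, mean revisit intervals rank ascending. NaN metric
    values mean "undefined" and always rank after every defined value.
    """

    labels: list[str]
    metric: np.ndarray
    ranks: np.ndarray
    algorithm: str
    direction_used: str = "forward"
    higher_is_better: bool = True

    @property
    def n(self) -> int:
        return len(self.labels)

    def rank_of(self, label: str) -> float:
        return float(self.ranks[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "metric": self.metric, "rank": self.ranks}
        )


class ConvergenceError(RuntimeError):
    """PageRank failed to converge; ``scores`` carries the last iterate."""

    def __init__(self, message: str, scores: np.ndarray):
        super().__init__(message)
        self.scores = scores


def make_ranking(
    labels,
    metric,
    algorithm: str,
    *,
    direction: str = "forward",
    higher_is_better: bool = True,
) -> NodeRanking:
    metric = np.asarray(metric, dtype=float)
    ranks = midranks(metric, descending=higher_is_better)
    return NodeRanking(
        list(labels), metric, ranks, algorithm, direction, higher_is_better
    )


def _transfer(x: np.ndarray, probs: np.ndarray, dangling: np.ndarray) -> np.ndarray:
    """One synchronous mass-transfer step.

    Each node sends its whole score split over outgoing edges proportionally
    to weight; a dangling node splits its score evenly over all OTHER nodes.
    Total mass is conserved exactly.
    """
    y = x @ probs
    if dangling.size:
        n = x.size
        xd = x[dangling]
        share = xd.sum() / (n - 1)
        y = y + share
        y[dangling] -= xd / (n - 1)
    return y


def pagerank(
    g: GCMap,
    damping: float = 0.85,
    *,
    reverse_edges: bool = False,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> NodeRanking:
    """Weighted PageRank scores (sum to 1), ranked descending.

    Each node's outflow is split proportionally to its outgoing GC weights;
    a dangling node's mass is spread evenly over all other nodes; the damped
    update is ``x <- damping * transfer(x) + (1 - damping)/N``. Iteration
    stops when the L1 change drops below ``tol``.

    With ``reverse_edges`` the map is transposed first, ranking generators
    of activity ("uphill") rather than receivers.
    """
    if not (0 < damping <= 1):
        raise ValueError("damping must be in (0, 1]")
    direction = "reverse" if reverse_edges else "forward"
    if reverse_edges:
        g = reverse(g)
    tm = to_transition(g)
    n = g.n
    if n == 1:
        return make_ranking(g.labels, [1.0], "pagerank", direction=direction)
    dang = np.fromiter(sorted(tm.dangling), dtype=int, count=len(tm.dangling))
    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for _ in range(max_iter):
        x_new = damping * _transfer(x, tm.probs, dang) + teleport
        if np.abs(x_new - x).sum() < tol:
            return make_ranking(g.labels, x_new, "pagerank", direction=direction)
        x = x_new
    raise ConvergenceError(f"pagerank did not converge in {max_iter} iterations", x)


def pagerank_didactic(g: GCMap, init: float = 10.0, iterations: int = 1) -> np.ndarray:
    """Undamped synchronous mass-transfer update, run for a fixed iteration count.

    Every node starts with score ``init`` (or a per-node array); each
    iteration every node transfers its entire score, split over outgoing
    edges by weight ratio, dangling nodes splitting evenly over all other
    nodes. No damping, no renormalization: total mass is conserved exactly.
    Returns the raw scores, in label order.
    """
    tm = to_transition(g)
    dang = np.fromiter(sorted(tm.dangling), dtype=int, count=len(tm.dangling))
    x = np.broadcast_to(np.asarray(init, dtype=float), (g.n,)).copy()
    for _ in range(iterations):
        x = _transfer(x, tm.probs, dang)
    return x


def to_networkx(g: GCMap) -> nx.DiGraph:
    """DiGraph with ``weight`` = GC magnitude and ``dist`` = 1/weight.

    Larger GC weight means a shorter, easier-to-take path; zero-weight edges
    are absent.
    """
    G = nx.DiGraph()
    G.add_nodes_from(g.labels)
    src, dst = np.nonzero(g.weights)
    for i, j in zip(src, dst):
        w = g.weights[i, j]
        G.add_edge(g.labels[i], g.labels[j], weight=w, dist=1.0 / w)
    return G


def betweenness(g: GCMap) -> NodeRanking:
    """Fraction of inverse-weight shortest directed paths passing through each node.

    For every ordered pair (p, q) with p != n != q, counts the share of
    shortest p->q paths (ties included) that transit n; ranked descending.
    """
    G = to_networkx(g)
    bc = nx.betweenness_centrality(G, weight="dist", normalized=False)
    metric = [bc[lbl] for lbl in g.labels]
    return make_ranking(g.labels, metric, "betweenness")


def harmonic(g: GCMap, *, distance: str = "inverse-weight", inward: bool = True) -> NodeRanking:
    """Mean inverse shortest-path distance into each node, ranked descending.

    harmonic(n) = sum over p != n of (1 / L_pn) / (N - 1), where L_pn is the
    shortest directed distance from p to n (edge length 1/weight by default,
    ``distance="hops"`` for unweighted); unreachable pairs contribute 0.
    ``inward=False`` measures distances out of n instead.
    """
    if distance not in ("inverse-weight", "hops"):
        raise ValueError("distance must be 'inverse-weight' or 'hops'")
    if not inward:
        g = reverse(g)
    G = to_networkx(g)
    dist = "dist" if distance == "inverse-weight" else None
    hc = nx.harmonic_centrality(G, distance=dist)
    denom = max(g.n - 1, 1)
    metric = [hc[lbl] / denom for lbl in g.labels]
    direction = "forward" if inward else "reverse"
    return make_ranking(g.labels, metric, "harmonic", direction=direction)


def degree_centrality(g: GCMap, mode: str = "out", *, weighted: bool = False) -> NodeRanking:
    """Count (default) or weight-sum of incoming/outgoing edges, ranked descending.

    The unweighted count over F-test-surviving edges isolates edge *quantity*
    from edge weight, the complementary signal to total GC outdegree.
    """
    if mode not in ("in", "out"):
        raise ValueError("mode must be 'in' or 'out'")
    # in-metrics reduce a contiguous transpose row-wise so that the in/out
    # reversal duality holds bit-exactly, not just mathematically
    w = g.weights if mode == "out" else np.ascontiguousarray(g.weights.T)
    metric = w.sum(axis=1) if weighted else (w > 0).sum(axis=1).astype(float)
    return make_ranking(g.labels, metric, f"{mode}degree")


def total_gc_outdegree(g: GCMap) -> NodeRanking:
    """Sum of each node's outgoing GC weights (baseline metric), ranked descending."""
    return make_ranking(g.labels, g.weights.sum(axis=1), "gc-outdegree")


def top_k(r: NodeRanking, k: int) -> set[str]:
    """The k best-ranked node labels; boundary ties break lexicographically."""
    if not (1 <= k <= r.n):
        raise ValueError(f"k must be in [1, {r.n}], got {k}")
    order = sorted(range(r.n), key=lambda i: (r.ranks[i], r.labels[i]))
    return {r.labels[i] for i in order[:k]}


#: Deterministic ranking algorithms by CLI identifier.
ALGORITHMS = {
    "pagerank": lambda g: pagerank(g),
    "pagerank-rev": lambda g: pagerank(g, reverse_edges=True),
    "betweenness": betweenness,
    "harmonic": harmonic,
    "indegree": lambda g: degree_centrality(g, "in"),
    "outdegree": lambda g: degree_centrality(g, "out"),
    "gc-outdegree": total_gc_outdegree,
}
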