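"""Centrality metrics against brute-force oracles and reversal dualities."""

import networkx as nx
import numpy as np
import pytest

from gcnet import (
    ConvergenceError,
    GCMap,
    betweenness,
    degree_centrality,
    harmonic,
    pagerank,
    pagerank_didactic,
    reverse,
    top_k,
    total_gc_outdegree,
)
from gcnet.ranking import ALGORITHMS, make_ranking


# ---------------------------------------------------------------------------
# brute-force shortest-path oracle (independent of networkx)
# ---------------------------------------------------------------------------

def make_integer_distance_map(rng, n, density=0.5):
    """Random digraph whose edge distances 1/weight are exact small integers,
    so shortest-path arithmetic is exact in floats and ties are exact."""
    dist = np.where(rng.random((n, n)) < density, rng.integers(1, 10, (n, n)), 0)
    np.fill_diagonal(dist, 0)
    w = np.zeros((n, n))
    w[dist > 0] = 1.0 / dist[dist > 0]
    return GCMap(w, [f"n{i}" for i in range(n)]), dist


def enumerate_shortest_paths(dist):
    """DFS over all simple paths: exact distances, path counts, transit counts.

    Returns dicts best[(p,q)] -> int distance, count[(p,q)] -> path count,
    through[(p,q)] -> {node: count of shortest p->q paths via node}.
    """
    n = dist.shape[0]
    best, count, through = {}, {}, {}

    def dfs(path, total, target):
        node = path[-1]
        if node == target and len(path) > 1:
            key = (path[0], target)
            if key not in best or total < best[key]:
                best[key], count[key] = total, 0
                through[key] = {}
            if total == best[key]:
                count[key] += 1
                for mid in path[1:-1]:
                    through[key][mid] = through[key].get(mid, 0) + 1
            return
        for nxt in range(n):
            if dist[node, nxt] > 0 and nxt not in path:
                dfs(path + [nxt], total + int(dist[node, nxt]), target)

    for p in range(n):
        for q in range(n):
            if p != q:
                dfs([p], 0, q)
    return best, count, through


def count_paths_floyd_warshall(dist):
    """Independent DP route to shortest distances and path counts."""
    n = dist.shape[0]
    INF = float("inf")
    d = np.full((n, n), INF)
    c = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] > 0:
                d[i, j] = int(dist[i, j])
                c[i, j] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if i == j or i == k or j == k:
                    continue
                alt = d[i, k] + d[k, j]
                if alt < d[i, j]:
                    d[i, j], c[i, j] = alt, c[i, k] * c[k, j]
                elif alt == d[i, j] and alt < INF:
                    c[i, j] += c[i, k] * c[k, j]
    return d, c


def brute_betweenness(dist):
    n = dist.shape[0]
    best, count, through = enumerate_shortest_paths(dist)
    metric = np.zeros(n)
    for (p, q), cnt in count.items():
        for node, hits in through[(p, q)].items():
            metric[node] += hits / cnt
    return metric


def brute_harmonic(dist):
    n = dist.shape[0]
    best, _, _ = enumerate_shortest_paths(dist)
    metric = np.zeros(n)
    for (p, q), d in best.items():
        metric[q] += 1.0 / d
    return metric / max(n - 1, 1)


@pytest.mark.parametrize("seed", range(12))
def test_betweenness_and_harmonic_match_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    g, dist = make_integer_distance_map(rng, n)
    assert np.allclose(betweenness(g).metric, brute_betweenness(dist), atol=1e-12)
    assert np.allclose(harmonic(g).metric, brute_harmonic(dist), atol=1e-12)


def test_enumeration_agrees_with_floyd_warshall_exactly():
    """The two independent oracle routes agree on distances and path counts."""
    rng = np.random.default_rng(123)
    for _ in range(10):
        n = int(rng.integers(3, 8))
        _, dist = make_integer_distance_map(rng, n)
        best, count, _ = enumerate_shortest_paths(dist)
        d, c = count_paths_floyd_warshall(dist)
        for p in range(n):
            for q in range(n):
                if p == q:
                    continue
                if (p, q) in best:
                    assert d[p, q] == best[(p, q)]
                    assert c[p, q] == count[(p, q)]
                else:
                    assert np.isinf(d[p, q])


# ---------------------------------------------------------------------------
# pagerank
# ---------------------------------------------------------------------------

def oracle_pagerank(g, damping=0.85, iters=5000):
    """Brute-force power iteration written independently of the library path."""
    n = g.n
    w = g.weights
    x = np.full(n, 1.0 / n)
    for _ in range(iters):
        y = np.zeros(n)
        for i in range(n):
            row = w[i]
            s = row.sum()
            if s > 0:
                y += x[i] * row / s
            else:
                share = x[i] / (n - 1)
                y += share
                y[i] -= share
        x = damping * y + (1 - damping) / n
    return x


@pytest.mark.parametrize("damping", [0.3, 0.85, 1.0])
def test_symmetric_cycle_is_uniform(cycle2, damping):
    r = pagerank(cycle2, damping)
    assert np.allclose(r.metric, [0.5, 0.5], atol=1e-9)


def test_pagerank_matches_power_iteration_oracle(paper_graph):
    r = pagerank(paper_graph, 0.85, tol=1e-14, max_iter=2000)
    assert np.allclose(r.metric, oracle_pagerank(paper_graph), atol=1e-10)


def test_pagerank_matches_networkx_without_dangling(make_random_gcmap):
    # networkx's dangling rule differs; on dangling-free graphs they coincide
    rng = np.random.default_rng(17)
    for _ in range(5):
        g = make_random_gcmap(rng, 9, density=0.5, ensure_no_dangling=True)
        G = nx.DiGraph()
        G.add_nodes_from(g.labels)
        for i, j in zip(*np.nonzero(g.weights)):
            G.add_edge(g.labels[i], g.labels[j], weight=g.weights[i, j])
        expected = nx.pagerank(G, alpha=0.85, weight="weight", tol=1e-12)
        r = pagerank(g, 0.85, tol=1e-12, max_iter=1000)
        assert np.allclose(r.metric, [expected[l] for l in g.labels], atol=1e-8)


def test_pagerank_scores_sum_to_one(make_random_gcmap):
    rng = np.random.default_rng(23)
    for _ in range(10):
        g = make_random_gcmap(rng, int(rng.integers(3, 20)), density=0.3)
        assert pagerank(g).metric.sum() == pytest.approx(1.0, abs=1e-9)


def test_pagerank_nonconvergence_carries_last_iterate(paper_graph):
    with pytest.raises(ConvergenceError) as exc:
        pagerank(paper_graph, tol=1e-300, max_iter=3)
    assert exc.value.scores.shape == (3,)


class TestDidactic:
    def test_worked_example(self, paper_graph):
        assert pagerank_didactic(paper_graph, 10.0, 1).tolist() == [15.0, 10.0, 5.0]
        assert pagerank_didactic(paper_graph, 10.0, 2).tolist() == [12.5, 10.0, 7.5]

    def test_mass_conserved(self, make_random_gcmap):
        rng = np.random.default_rng(31)
        for _ in range(5):
            g = make_random_gcmap(rng, 7, density=0.4)
            scores = pagerank_didactic(g, 10.0, 6)
            assert scores.sum() == pytest.approx(70.0, abs=1e-9)


# ---------------------------------------------------------------------------
# other centralities
# ---------------------------------------------------------------------------

def test_betweenness_transit_node_only():
    w = np.array([[0, 1.0, 0], [0, 0, 1.0], [0, 0, 0]])
    g = GCMap(w, ["a", "b", "c"])
    m = betweenness(g).metric
    assert m[1] > 0 and m[0] == 0 and m[2] == 0


def test_equal_weight_betweenness_is_unweighted(make_random_gcmap):
    rng = np.random.default_rng(19)
    w = (rng.random((7, 7)) < 0.4).astype(float) * 2.5
    np.fill_diagonal(w, 0)
    g = GCMap(w, [f"n{i}" for i in range(7)])
    G = nx.from_numpy_array(w > 0, create_using=nx.DiGraph)
    unweighted = nx.betweenness_centrality(G, normalized=False)
    assert np.allclose(betweenness(g).metric, [unweighted[i] for i in range(7)])


def test_harmonic_two_cycle_and_isolated(cycle2):
    assert np.allclose(harmonic(cycle2).metric, [1.0, 1.0])
    g = GCMap(np.zeros((3, 3)), list("abc"))
    assert np.all(harmonic(g).metric == 0)


def test_harmonic_hops_and_outward_variants(make_random_gcmap):
    rng = np.random.default_rng(29)
    g = make_random_gcmap(rng, 6, density=0.5)
    hops_in = harmonic(g, distance="hops")
    hops_out = harmonic(g, distance="hops", inward=False)
    rev = harmonic(reverse(g), distance="hops")
    assert np.allclose(hops_out.metric, rev.metric)
    assert hops_in.ranks.sum() == 21.0


def test_degree_centrality_star_and_empty():
    w = np.zeros((6, 6))
    w[0, 1:] = 2.0
    g = GCMap(w, [f"n{i}" for i in range(6)])
    out = degree_centrality(g, "out")
    assert out.metric[0] == 5 and np.all(out.metric[1:] == 0)
    empty = degree_centrality(GCMap(np.zeros((4, 4)), list("abcd")), "in")
    assert np.all(empty.metric == 0)
    assert np.all(empty.ranks == 2.5)


def test_total_gc_outdegree_row_sums_and_binary_equivalence():
    w = np.array([[0, 0.2, 0.3], [0, 0, 0], [0.1, 0, 0]])
    g = GCMap(w, list("abc"))
    assert np.allclose(total_gc_outdegree(g).metric, [0.5, 0, 0.1])
    binary = GCMap((w > 0).astype(float), list("abc"))
    assert np.array_equal(
        total_gc_outdegree(binary).metric, degree_centrality(binary, "out").metric
    )


def test_weighted_degree_option_equals_total_outdegree(make_random_gcmap):
    rng = np.random.default_rng(41)
    g = make_random_gcmap(rng, 8)
    assert np.allclose(
        degree_centrality(g, "out", weighted=True).metric,
        total_gc_outdegree(g).metric,
    )


# ---------------------------------------------------------------------------
# ranks, top-k, dualities
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", sorted(ALGORITHMS))
def test_midrank_sum_identity(name, make_random_gcmap):
    rng = np.random.default_rng(abs(hash(name)) % 1000)
    g = make_random_gcmap(rng, 12, density=0.3)
    r = ALGORITHMS[name](g)
    assert r.ranks.sum() == pytest.approx(12 * 13 / 2, abs=1e-9)
    assert r.ranks.min() >= 1 and r.ranks.max() <= 12


def test_rank_one_is_best_metric(make_random_gcmap):
    rng = np.random.default_rng(53)
    g = make_random_gcmap(rng, 10, density=0.6)
    r = total_gc_outdegree(g)
    assert r.metric[np.argmin(r.ranks)] == r.metric.max()


class TestTopK:
    def test_basic_and_full(self):
        r = make_ranking(list("abc"), [3.0, 2.0, 1.0], "x")
        assert top_k(r, 2) == {"a", "b"}
        assert top_k(r, 3) == {"a", "b", "c"}

    def test_boundary_tie_lexicographic(self):
        r = make_ranking(list("acb"), [3.0, 1.0, 1.0], "x")
        assert top_k(r, 2) == {"a", "b"}

    @pytest.mark.parametrize("k", [0, 4])
    def test_out_of_range(self, k):
        r = make_ranking(list("abc"), [3.0, 2.0, 1.0], "x")
        with pytest.raises(ValueError):
            top_k(r, k)


def test_reversal_dualities_exact(make_random_gcmap):
    rng = np.random.default_rng(61)
    g = make_random_gcmap(rng, 10, density=0.4)
    rg = reverse(g)
    assert np.array_equal(
        degree_centrality(g, "out").metric, degree_centrality(rg, "in").metric
    )
    assert np.array_equal(
        total_gc_outdegree(g).metric,
        degree_centrality(rg, "in", weighted=True).metric,
    )
    assert np.allclose(total_gc_outdegree(rg).metric, g.weights.sum(axis=0),
                       rtol=1e-12)
    fwd = pagerank(g, reverse_edges=True)
    rev = pagerank(rg)
    assert np.array_equal(fwd.metric, rev.metric)
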