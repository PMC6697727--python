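import itertools

import numpy as np
import pytest

from ttwsurrogate import (
    COARSE,
    CommuterNetwork,
    adjacency_views,
    avg_shortest_path,
    correlation_2d,
    intersect,
    mse_overlap,
    strength_distribution,
    weight_histogram,
    weighted_clustering,
)
from conftest import random_network


def views_from_arrays(a, b):
    nodes = [f"n{i}" for i in range(a.shape[0])]
    from ttwsurrogate.validation import AdjacencyView
    return AdjacencyView(nodes, a), AdjacencyView(nodes, b)


def test_correlation_identity_and_scale_invariance():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 20, (6, 6))
    va, vb = views_from_arrays(a, a)
    assert correlation_2d(va, vb) == pytest.approx(1.0, abs=1e-12)
    va, vb = views_from_arrays(a, 2 * a)
    assert correlation_2d(va, vb) == pytest.approx(1.0, abs=1e-12)


def test_correlation_symmetric_and_matches_two_pass():
    rng = np.random.default_rng(1)
    a = rng.integers(0, 30, (3, 3)).astype(float)
    b = rng.integers(0, 30, (3, 3)).astype(float)
    va, vb = views_from_arrays(a, b)
    # brute-force two-pass Pearson over the 9 cells
    am, bm = a.mean(), b.mean()
    num = sum((a[i, j] - am) * (b[i, j] - bm) for i in range(3) for j in range(3))
    den = np.sqrt(
        sum((a[i, j] - am) ** 2 for i in range(3) for j in range(3))
        * sum((b[i, j] - bm) ** 2 for i in range(3) for j in range(3))
    )
    assert correlation_2d(va, vb) == pytest.approx(num / den, abs=1e-12)
    assert correlation_2d(vb, va) == pytest.approx(correlation_2d(va, vb), abs=1e-15)


def test_correlation_zero_variance_is_nan():
    va, vb = views_from_arrays(np.ones((3, 3)), np.arange(9.0).reshape(3, 3))
    assert np.isnan(correlation_2d(va, vb))


def test_adjacency_views_share_ordering_and_totals():
    a = CommuterNetwork(COARSE, COARSE, {("A", "B"): 2, ("B", "A"): 5})
    b = CommuterNetwork(COARSE, COARSE, {("A", "C"): 7})
    va, vb = adjacency_views(a, b)
    assert va.nodes == vb.nodes == ["A", "B", "C"]
    assert va.total == a.total_commuters and vb.total == b.total_commuters


def test_mse_hand_example_and_brute_force():
    b = CommuterNetwork(COARSE, COARSE, {("A", "D"): 5, ("B", "E"): 2})
    a = CommuterNetwork(COARSE, COARSE, {("A", "D"): 3, ("B", "E"): 2})
    assert mse_overlap(intersect(b, a)) == pytest.approx(2.0, abs=1e-15)
    assert mse_overlap(intersect(b, b)) == 0.0
    rng = np.random.default_rng(4)
    left, right = random_network(rng), random_network(rng)
    ov = intersect(left, right)
    brute = sum((left.edges[e] - right.edges[e]) ** 2 for e in ov.shared) / len(ov)
    assert mse_overlap(ov) == pytest.approx(brute, abs=1e-12)
    with pytest.raises(ValueError):
        mse_overlap(intersect(
            CommuterNetwork(COARSE, COARSE, {("A", "D"): 1}),
            CommuterNetwork(COARSE, COARSE, {("Z", "Z"): 1}),
        ))


def test_clustering_triangle_and_star():
    tri = CommuterNetwork(
        COARSE, COARSE, {("A", "B"): 4, ("B", "C"): 4, ("C", "A"): 4}
    )
    assert weighted_clustering(tri) == pytest.approx(1.0, abs=1e-12)
    star = CommuterNetwork(
        COARSE, COARSE, {("H", "A"): 3, ("H", "B"): 5, ("H", "C"): 2}
    )
    assert weighted_clustering(star) == 0.0


def brute_clustering(net):
    """Naive triple loop over the undirected unipartite view."""
    und = {}
    for (o, d), w in net.edges.items():
        if o == d:
            continue
        k = tuple(sorted((o, d)))
        und[k] = und.get(k, 0) + w
    nodes = sorted({z for e in und for z in e})
    w_max = max(und.values())
    w_hat = {k: v / w_max for k, v in und.items()}

    def wh(a, b):
        return w_hat.get(tuple(sorted((a, b))), 0.0)

    total = 0.0
    for i in nodes:
        nbrs = [n for n in nodes if n != i and wh(i, n) > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = sum(
            (wh(i, j) * wh(j, l) * wh(l, i)) ** (1 / 3)
            for j, l in itertools.combinations(nbrs, 2)
        )
        total += 2 * s / (k * (k - 1))
    return total / len(nodes)


def test_clustering_matches_brute_force():
    rng = np.random.default_rng(6)
    for _ in range(5):
        net = random_network(rng, 12, 12, 0.3)
        assert weighted_clustering(net) == pytest.approx(
            brute_clustering(net), abs=1e-12
        )


def brute_paths(net):
    """Exhaustive simple-path enumeration, distance = 1/w."""
    adj = {}
    for (o, d), w in net.edges.items():
        if o != d:
            adj.setdefault(o, {})[d] = 1.0 / w
    nodes = sorted({z for e in net.edges for z in e if e[0] != e[1]})
    best = {}

    def dfs(start, cur, cost, seen):
        for nxt, c in adj.get(cur, {}).items():
            if nxt in seen:
                continue
            key = (start, nxt)
            if key not in best or cost + c < best[key]:
                best[key] = cost + c
            dfs(start, nxt, cost + c, seen | {nxt})

    for n in nodes:
        dfs(n, n, 0.0, {n})
    unreachable = len(nodes) * (len(nodes) - 1) - len(best)
    return sum(best.values()) / len(best), unreachable


def test_shortest_path_hand_cases():
    two = CommuterNetwork(COARSE, COARSE, {("A", "B"): 4})
    mean, unreachable = avg_shortest_path(two)
    assert mean == pytest.approx(0.25, abs=1e-15)
    assert unreachable == 1  # B cannot reach A in the directed view
    detour = CommuterNetwork(
        COARSE, COARSE, {("A", "B"): 2, ("B", "C"): 2, ("A", "C"): 1}
    )
    # d(A,C) = min(1/1, 1/2 + 1/2) = 1.0; d(A,B)=0.5; d(B,C)=0.5
    mean, unreachable = avg_shortest_path(detour)
    assert mean == pytest.approx((1.0 + 0.5 + 0.5) / 3, abs=1e-12)


def test_shortest_path_matches_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(5):
        net = random_network(rng, 8, 8, 0.25)
        got = avg_shortest_path(net)
        want = brute_paths(net)
        assert got[0] == pytest.approx(want[0], abs=1e-12)
        assert got[1] == want[1]


def test_weight_histogram_and_strengths():
    net = CommuterNetwork(COARSE, COARSE, {("A", "B"): 5})
    h = weight_histogram(net, bin_width=10)
    assert h["count"].sum() == 1
    assert h.loc[h["count"] == 1, "bin_lo"].item() == 0
    assert weight_histogram(CommuterNetwork(COARSE, COARSE, {})).empty
    rng = np.random.default_rng(3)
    net = random_network(rng)
    h = weight_histogram(net, bin_width=7)
    assert int(h["count"].sum()) == net.n_edges
    s = strength_distribution(net, bin_width=25)
    nodes = {z for e in net.edges for z in e}
    assert int(s["count"].sum()) == len(nodes)
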