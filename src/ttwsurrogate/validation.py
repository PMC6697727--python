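"""Network comparison metrics for validating a reconstruction.

The aggregated surrogate C is compared against the trusted coarse release B
and the aggregate A of the perturbed fine release through:

* the 2D (Pearson) correlation of their dense adjacency matrices over a
  shared node ordering;
* the mean-squared error of edge weights over the overlap edge set E_AB;
* average weighted clustering (Onnela form, weights scaled by the global
  maximum) and average weighted shortest path (Dijkstra with edge weight
  interpreted as inverse distance), treating the coarse commuter matrix as a
  unipartite weighted graph with origin and destination code spaces
  identified;
* edge-weight and node-strength histograms.

These are standard diagnostics; clustering and shortest paths are delegated
to networkx, the rest is direct numpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .network import CommuterNetwork, EdgeOverlap, intersect


@dataclass
class AdjacencyView:
    """Dense weight matrix of a coarse network over a fixed node ordering."""

    nodes: List[str]
    matrix: np.ndarray

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def adjacency_views(*nets: CommuterNetwork) -> List[AdjacencyView]:
    """Dense views of several networks over one shared node ordering.

    The node set is the union of origin and destination codes across all
    networks (unipartite identification of the two sides), sorted; this
    guarantees cell-by-cell comparability of the returned matrices.
    """
    nodes = sorted({z for net in nets for edge in net.edges for z in edge})
    index = {z: i for i, z in enumerate(nodes)}
    views = []
    for net in nets:
        m = np.zeros((len(nodes), len(nodes)), dtype=np.int64)
        for (o, d), w in net.edges.items():
            m[index[o], index[d]] = w
        views.append(AdjacencyView(nodes, m))
    return views


def correlation_2d(a: AdjacencyView, b: AdjacencyView) -> float:
    """Pearson product-moment correlation over all matrix cells.

    Returns NaN when either matrix has zero variance (the correlation is
    undefined there, and reported as such rather than guessed).
    """
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("adjacency views must share shape and ordering")
    x = a.matrix.astype(float).ravel()
    y = b.matrix.astype(float).ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float((xc @ yc) / denom)


def mse_overlap(overlap: EdgeOverlap) -> float:
    """Mean squared weight difference over the shared edge set."""
    if len(overlap) == 0:
        raise ValueError("overlap is empty; MSE undefined")
    diff = overlap.weights_left.astype(float) - overlap.weights_right.astype(float)
    return float(np.mean(diff * diff))


def restrict_to_edges(net: CommuterNetwork, edges: Sequence[Tuple[str, str]]
                      ) -> CommuterNetwork:
    """Sub-network of ``net`` on the given keys (missing keys are skipped)."""
    sub = {e: net.edges[e] for e in edges if e in net.edges}
    return CommuterNetwork(net.origin_level, net.dest_level, sub)


def _as_undirected_graph(net: CommuterNetwork) -> nx.Graph:
    """Unipartite undirected view: opposite-direction weights summed, self-loops dropped."""
    g = nx.Graph()
    for (o, d), w in net.edges.items():
        if o == d:
            continue
        if g.has_edge(o, d):
            g[o][d]["weight"] += w
        else:
            g.add_edge(o, d, weight=w)
    return g


def weighted_clustering(net: CommuterNetwork) -> float:
    """Average weighted clustering coefficient of the unipartite view.

    Per node, C_i = (2 / (k_i (k_i − 1))) Σ_{j<k} (ŵ_ij ŵ_jk ŵ_ki)^{1/3}
    with ŵ scaled by the largest weight in the network; nodes of degree < 2
    contribute 0, and the average runs over all nodes.
    """
    g = _as_undirected_graph(net)
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(g, weight="weight", count_zeros=True))


def avg_shortest_path(
    net: CommuterNetwork, symmetrize: bool = False
) -> Tuple[float, int]:
    """Average Dijkstra shortest path with edge weight as inverse distance.

    Returns (mean over ordered reachable pairs of distinct nodes, number of
    unreachable ordered pairs).  Unreachable pairs are excluded from the
    mean, not assigned infinity.  The graph is directed unless
    ``symmetrize`` is set (which sums opposite-direction weights).
    """
    if symmetrize:
        g: nx.Graph = _as_undirected_graph(net)
        for o, d, data in g.edges(data=True):
            data["dist"] = 1.0 / data["weight"]
    else:
        g = nx.DiGraph()
        for (o, d), w in net.edges.items():
            if o == d:
                continue
            g.add_edge(o, d, dist=1.0 / w)
    n = g.number_of_nodes()
    if n < 2:
        return (float("nan"), 0)
    total = 0.0
    reachable = 0
    for _, lengths in nx.all_pairs_dijkstra_path_length(g, weight="dist"):
        total += sum(lengths.values())
        reachable += len(lengths) - 1  # drop the source itself
    ordered_pairs = n * (n - 1)
    if reachable == 0:
        return (float("nan"), ordered_pairs)
    return (total / reachable, ordered_pairs - reachable)


def weight_histogram(
    net: CommuterNetwork, bin_width: int = 1, w_max: Optional[int] = None
) -> pd.DataFrame:
    """Edge counts per weight bin [lo, lo + bin_width); Σ counts == |E|."""
    if net.n_edges == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
    ws = np.fromiter(net.edges.values(), dtype=np.int64)
    top = int(w_max) if w_max is not None else int(ws.max())
    edges = np.arange(0, top + 2 * bin_width, bin_width)
    counts, _ = np.histogram(np.minimum(ws, top), bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )


def strength_distribution(net: CommuterNetwork, bin_width: int = 10) -> pd.DataFrame:
    """Histogram of total incident node strength (in + out); Σ counts == #nodes."""
    strengths: Dict[str, int] = {}
    for (o, d), w in net.edges.items():
        strengths[o] = strengths.get(o, 0) + w
        strengths[d] = strengths.get(d, 0) + w
    if not strengths:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
    vals = np.fromiter(strengths.values(), dtype=np.int64)
    edges = np.arange(0, int(vals.max()) + 2 * bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})


def validation_report(
    A: CommuterNetwork, B: CommuterNetwork, C: CommuterNetwork
) -> Dict[str, object]:
    """All pairwise metrics for the (A, B, C) coarse-network triple.

    A is the aggregate of the perturbed fine release, B the trusted coarse
    release, C the aggregate of the surrogate.  MSEs are computed over the
    overlap E_AB (which equals E_B ∩ E_C because the reconstruction adds no
    coarse edges outside it); clustering and shortest paths are reported on
    the E_AB-restricted networks A*, B*, C* and on full B.
    """
    va, vb, vc = adjacency_views(A, B, C)
    ov_ba = intersect(B, A)
    ov_bc = intersect(B, C)
    ov_ac = intersect(A, C)
    e_ab = ov_ba.shared
    a_star = restrict_to_edges(A, e_ab)
    b_star = restrict_to_edges(B, e_ab)
    c_star = restrict_to_edges(C, e_ab)
    path_a, unreach_a = avg_shortest_path(a_star)
    path_b, unreach_b = avg_shortest_path(b_star)
    path_c, unreach_c = avg_shortest_path(c_star)
    path_b_full, unreach_b_full = avg_shortest_path(B)
    return {
        "totals": {"A": A.total_commuters, "B": B.total_commuters,
                   "C": C.total_commuters},
        "n_edges": {"A": A.n_edges, "B": B.n_edges, "C": C.n_edges,
                    "E_AB": len(e_ab)},
        "correlation_2d": {
            "B_A": correlation_2d(vb, va),
            "B_C": correlation_2d(vb, vc),
            "A_C": correlation_2d(va, vc),
        },
        "mse_overlap": {
            "B_A": mse_overlap(ov_ba),
            "B_C": mse_overlap(ov_bc),
            "A_C": mse_overlap(ov_ac),
        },
        "clustering": {
            "A_star": weighted_clustering(a_star),
            "C_star": weighted_clustering(c_star),
            "B_star": weighted_clustering(b_star),
            "B": weighted_clustering(B),
        },
        "shortest_path": {
            "A_star": path_a, "C_star": path_c, "B_star": path_b, "B": path_b_full,
            "unreachable_pairs": {
                "A_star": unreach_a, "C_star": unreach_c,
                "B_star": unreach_b, "B": unreach_b_full,
            },
        },
    }
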