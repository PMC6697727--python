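"""Weighted bipartite commuter networks and scale aggregation.

A commuter (travel-to-work) network is a bipartite graph G = (X ∪ Y, E) whose
edge (x, y) carries the integer number of commuters w(x, y) travelling from
residential zone x to workplace zone y.  Networks are tagged with the
partition level of each side ("fine" or "coarse"), and all weights are kept
as positive integers: an edge exists if and only if its key is present, and
every arithmetic operation in this module is exact integer arithmetic.

The central operations are:

* :func:`aggregate` — amalgamate a network to coarser partitions through a
  :class:`~ttwsurrogate.geography.ZoneHierarchy`, conserving total commuters
  exactly;
* :func:`intersect` / :func:`weight_discrepancies` — the overlap edge set
  E_AB of two same-level networks and the per-edge weight discrepancies
  Δw = w_B − w_A on it;
* :func:`missing_edges` — the sub-network of edges present on one side only.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

import numpy as np

from .geography import DEST, ORIGIN, ZoneHierarchy

FINE = "fine"
COARSE = "coarse"
_LEVEL_ORDER = {FINE: 0, COARSE: 1}

Edge = Tuple[str, str]


class LevelError(ValueError):
    """Two networks (or a requested aggregation) disagree on partition levels."""


def _check_level(level: str) -> None:
    if level not in _LEVEL_ORDER:
        raise ValueError(f"unknown partition level {level!r}; expected 'fine' or 'coarse'")


@dataclass
class CommuterNetwork:
    """Sparse weighted bipartite edge list at a declared partition pair."""

    origin_level: str
    dest_level: str
    edges: Dict[Edge, int]

    def __post_init__(self) -> None:
        _check_level(self.origin_level)
        _check_level(self.dest_level)
        for key, w in self.edges.items():
            if not isinstance(w, (int, np.integer)) or isinstance(w, bool):
                raise TypeError(f"edge {key} has non-integer weight {w!r}")
            if w < 1:
                raise ValueError(f"edge {key} has weight {w} < 1")
        self.edges = {k: int(w) for k, w in self.edges.items()}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_commuters(self) -> int:
        """N_G = Σ w(E_G, G)."""
        return sum(self.edges.values())

    @property
    def levels(self) -> Tuple[str, str]:
        return (self.origin_level, self.dest_level)

    def sorted_edges(self) -> Iterator[Tuple[Edge, int]]:
        """Canonical (lexicographic) edge iteration for reproducible output."""
        for key in sorted(self.edges):
            yield key, self.edges[key]

    def copy(self) -> "CommuterNetwork":
        return CommuterNetwork(self.origin_level, self.dest_level, dict(self.edges))

    def out_strengths(self) -> Dict[str, int]:
        """Total out-weight per origin (the accumulated worker count N_x^R)."""
        acc: Dict[str, int] = defaultdict(int)
        for (x, _), w in self.edges.items():
            acc[x] += w
        return dict(acc)

    def in_strengths(self) -> Dict[str, int]:
        """Total in-weight per destination."""
        acc: Dict[str, int] = defaultdict(int)
        for (_, y), w in self.edges.items():
            acc[y] += w
        return dict(acc)


@dataclass
class EdgeOverlap:
    """The shared edge set E_AB = E_B ∩ E_A with both weight vectors.

    ``weights_left`` / ``weights_right`` are indexed to ``shared`` and, by
    the convention of the discrepancy definition Δw = w_B − w_A, the left
    network is the trusted coarse release B and the right one the aggregate A.
    """

    shared: List[Edge]
    weights_left: np.ndarray
    weights_right: np.ndarray
    levels: Tuple[str, str] = field(default=(COARSE, COARSE))

    def __post_init__(self) -> None:
        self.weights_left = np.asarray(self.weights_left, dtype=np.int64)
        self.weights_right = np.asarray(self.weights_right, dtype=np.int64)
        if not (len(self.shared) == len(self.weights_left) == len(self.weights_right)):
            raise ValueError("shared edges and weight vectors must have equal length")

    def __len__(self) -> int:
        return len(self.shared)


def aggregate(
    net: CommuterNetwork,
    hierarchy: ZoneHierarchy,
    to_origin_level: str = COARSE,
    to_dest_level: str = COARSE,
) -> CommuterNetwork:
    """Amalgamate ``net`` to coarser partition levels.

    Each output edge weight is the exact integer sum of the input edge
    weights whose endpoints map into that coarse pair; total commuters are
    conserved.  Requesting the network's own levels returns a copy.
    """
    _check_level(to_origin_level)
    _check_level(to_dest_level)
    if _LEVEL_ORDER[to_origin_level] < _LEVEL_ORDER[net.origin_level]:
        raise LevelError(
            f"cannot disaggregate origins from {net.origin_level!r} to {to_origin_level!r}"
        )
    if _LEVEL_ORDER[to_dest_level] < _LEVEL_ORDER[net.dest_level]:
        raise LevelError(
            f"cannot disaggregate destinations from {net.dest_level!r} to {to_dest_level!r}"
        )
    map_origin = to_origin_level != net.origin_level
    map_dest = to_dest_level != net.dest_level
    if not (map_origin or map_dest):
        return net.copy()

    out: Dict[Edge, int] = defaultdict(int)
    for (x, y), w in net.edges.items():
        xo = hierarchy.parent_of(x, ORIGIN) if map_origin else x
        yo = hierarchy.parent_of(y, DEST) if map_dest else y
        out[(xo, yo)] += w
    return CommuterNetwork(to_origin_level, to_dest_level, dict(out))


def _check_same_levels(left: CommuterNetwork, right: CommuterNetwork) -> None:
    if left.levels != right.levels:
        raise LevelError(
            f"networks are at different partition levels: {left.levels} vs {right.levels}"
        )


def intersect(left: CommuterNetwork, right: CommuterNetwork) -> EdgeOverlap:
    """Overlap E_AB of two same-level networks, weights preserved per side."""
    _check_same_levels(left, right)
    shared = sorted(left.edges.keys() & right.edges.keys())
    wl = np.array([left.edges[e] for e in shared], dtype=np.int64)
    wr = np.array([right.edges[e] for e in shared], dtype=np.int64)
    return EdgeOverlap(shared, wl, wr, levels=left.levels)


def weight_discrepancies(overlap: EdgeOverlap) -> Dict[Edge, int]:
    """Per-edge discrepancy Δw = w_left − w_right over the shared edge set."""
    diff = overlap.weights_left - overlap.weights_right
    return {e: int(d) for e, d in zip(overlap.shared, diff)}


def missing_edges(left: CommuterNetwork, right: CommuterNetwork) -> CommuterNetwork:
    """Sub-network of ``left`` on keys absent from ``right`` (E_left \\ E_right)."""
    _check_same_levels(left, right)
    only = {e: w for e, w in left.edges.items() if e not in right.edges}
    return CommuterNetwork(left.origin_level, left.dest_level, only)


def out_strengths(net: CommuterNetwork) -> Dict[str, int]:
    return net.out_strengths()


def in_strengths(net: CommuterNetwork) -> Dict[str, int]:
    return net.in_strengths()
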