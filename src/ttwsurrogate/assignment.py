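"""Constrained assignment of candidate edges to fine destinations.

The second stage of the reconstruction walks the fine destinations and, for
each, samples one candidate edge uniformly from the subset M′ of candidates
whose origin is topologically compatible with that destination, then accepts
it only if both quantitative constraints hold:

* the coarse-edge budget — adding the edge must not push the aggregate of
  the surrogate above the trusted coarse network's weight on the coarse
  (origin, destination) pair, i.e. w* ≤ Δw remaining on that pair;
* the destination capacity — the surrogate's in-strength at the destination
  must not exceed its known worker population, i.e. w* ≤ N_y minus the
  in-strength already assigned there.

Topological compatibility (the allowed-origin sets) comes from the mixed
coarse-origin → fine-destination network Γ intersected with the overlap edge
set E_AB of the coarse networks: a fine origin x may feed destination y only
if Γ contains (parent(x), y) and E_AB contains (parent(x), parent(y)).
Destinations are swept in a fresh random order each pass; a rejected
candidate stays in M and may be retried elsewhere.  The run terminates when
a full sweep accepts nothing (or a sweep cap is reached), normally leaving a
nonzero remainder of unassignable commuters — infeasibility is a normal
terminal state, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .candidates import CandidateEdge
from .geography import DEST, ORIGIN, ZoneHierarchy
from .network import (
    CommuterNetwork,
    EdgeOverlap,
    aggregate,
    intersect,
    weight_discrepancies,
)

Edge = Tuple[str, str]


@dataclass
class AllowedOrigins:
    """Per fine destination, the set of fine origins compatible with Γ and E_AB."""

    by_destination: Dict[str, FrozenSet[str]]


def build_allowed_origins(
    gamma: CommuterNetwork,
    overlap: EdgeOverlap,
    hierarchy: ZoneHierarchy,
) -> AllowedOrigins:
    """Compute the allowed fine-origin set X_Φ for every destination in Γ.

    For destination y, the compatible coarse origins Φ are those with a Γ
    edge into y whose coarse pair (Φ, parent(y)) also lies in the overlap
    E_AB; the allowed fine origins are all children of Φ.  Destinations
    whose sets come out empty are retained (they simply never accept).
    """
    shared = set(overlap.shared)
    allowed: Dict[str, set] = {}
    for (coarse_o, y) in gamma.edges:
        allowed.setdefault(y, set())
        parent_y = hierarchy.parent_of(y, DEST)
        if (coarse_o, parent_y) in shared:
            allowed[y].update(hierarchy.children_of(coarse_o, ORIGIN))
    return AllowedOrigins({y: frozenset(s) for y, s in allowed.items()})


@dataclass
class BudgetLedger:
    """Remaining coarse-edge budgets and destination capacities.

    ``coarse_budget`` starts from the weight discrepancies Δw = w(E_AB, B) −
    w(E_AB, A) on the overlap (non-positive entries never accept anything);
    ``dest_capacity`` starts from N_y minus the in-strength the input fine
    network already places at y (the surrogate is initialised as a copy of
    that network, so its in-strength counts against the capacity from the
    start).
    """

    coarse_budget: Dict[Edge, int]
    dest_capacity: Dict[str, int]

    def can_accept(self, coarse_pair: Edge, dest: str, w: int) -> bool:
        return (
            w <= self.coarse_budget.get(coarse_pair, 0)
            and w <= self.dest_capacity.get(dest, 0)
        )

    def accept(self, coarse_pair: Edge, dest: str, w: int) -> None:
        self.coarse_budget[coarse_pair] -= w
        self.dest_capacity[dest] -= w
        if self.coarse_budget[coarse_pair] < 0 or self.dest_capacity[dest] < 0:
            raise RuntimeError("ledger went negative: accept() without can_accept()")


def initialize_ledger(
    R: CommuterNetwork,
    B: CommuterNetwork,
    dest_populations: Dict[str, int],
    hierarchy: ZoneHierarchy,
    aggregated: Optional[CommuterNetwork] = None,
) -> Tuple[BudgetLedger, EdgeOverlap]:
    """Build the ledger from the fine release R, coarse release B, and N_Y."""
    A = aggregated if aggregated is not None else aggregate(R, hierarchy)
    overlap = intersect(B, A)
    budget = weight_discrepancies(overlap)
    in_str = R.in_strengths()
    capacity = {
        y: int(n) - in_str.get(y, 0) for y, n in dest_populations.items()
    }
    return BudgetLedger(budget, capacity), overlap


def merge_edge(edges: Dict[Edge, int], key: Edge, w: int) -> bool:
    """Add weight ``w`` onto ``key``; return True if a new key was created."""
    if key in edges:
        edges[key] += w
        return False
    edges[key] = w
    return True


@dataclass
class AssignmentResult:
    surrogate: CommuterNetwork
    unassigned: List[CandidateEdge]
    trace: List[int]            # unassigned commuters: initial, then per sweep
    sweeps: int
    accepted_count: int
    accepted_weight: int
    new_edges: int              # accepted candidates that created a new key
    termination: str            # "converged" or "sweep_cap"

    @property
    def unassigned_weight(self) -> int:
        return sum(c.weight for c in self.unassigned)


def assign_candidates(
    R: CommuterNetwork,
    candidates: Sequence[CandidateEdge],
    allowed: AllowedOrigins,
    ledger: BudgetLedger,
    hierarchy: ZoneHierarchy,
    seed: int,
    max_sweeps: int = 1_000_000,
    time_budget: Optional[float] = None,
) -> AssignmentResult:
    """Assign candidates to destinations, producing the surrogate network.

    The surrogate starts as a copy of R; each sweep visits every destination
    once in a fresh random permutation, samples one compatible candidate
    uniformly, and accepts it iff the ledger allows.  Accepted candidates
    are removed from M; rejected ones remain available.  Deterministic for a
    fixed seed (when ``time_budget``, an optional wall-clock cap in seconds
    checked between sweeps, is left off).
    """
    import time

    deadline = None if time_budget is None else time.monotonic() + time_budget
    rng = np.random.Generator(np.random.PCG64(int(seed) & 0x7FFFFFFF))
    surrogate_edges = dict(R.edges)

    # Per-origin stacks of outstanding candidate weights, indexed densely so
    # per-destination availability counts can be gathered as numpy fancy
    # indexing (the sweep's hot loop).
    origins = sorted({c.origin for c in candidates})
    origin_index = {x: i for i, x in enumerate(origins)}
    stacks: List[List[int]] = [[] for _ in origins]
    for c in candidates:
        stacks[origin_index[c.origin]].append(int(c.weight))
    alive = np.array([len(s) for s in stacks], dtype=np.int64)

    destinations = sorted(allowed.by_destination)
    dest_allowed_idx: List[np.ndarray] = []
    dest_parent: List[str] = []
    for y in destinations:
        idx = np.array(
            sorted(origin_index[x] for x in allowed.by_destination[y] if x in origin_index),
            dtype=np.intp,
        )
        dest_allowed_idx.append(idx)
        dest_parent.append(hierarchy.parent_of(y, DEST) if idx.size else "")

    remaining = int(sum(sum(s) for s in stacks))
    trace = [remaining]
    accepted_count = 0
    accepted_weight = 0
    new_edges = 0
    sweeps = 0
    termination = "converged"

    n_dest = len(destinations)
    while True:
        if sweeps >= max_sweeps:
            termination = "sweep_cap"
            break
        if deadline is not None and time.monotonic() >= deadline:
            termination = "time_budget"
            break
        accepted_this_sweep = 0
        for d in rng.permutation(n_dest):
            idx = dest_allowed_idx[d]
            if idx.size == 0:
                continue
            counts = alive[idx]
            total = int(counts.sum())
            if total == 0:
                continue
            # uniform over M′: origin ∝ outstanding count, then uniform within
            r = int(rng.integers(total))
            pos = int(np.searchsorted(np.cumsum(counts), r, side="right"))
            oi = int(idx[pos])
            stack = stacks[oi]
            j = int(rng.integers(len(stack)))
            w = stack[j]
            y = destinations[d]
            coarse_pair = (hierarchy.parent_of(origins[oi], ORIGIN), dest_parent[d])
            if not ledger.can_accept(coarse_pair, y, w):
                continue
            ledger.accept(coarse_pair, y, w)
            stack[j] = stack[-1]
            stack.pop()
            alive[oi] -= 1
            remaining -= w
            accepted_count += 1
            accepted_weight += w
            if merge_edge(surrogate_edges, (origins[oi], y), w):
                new_edges += 1
            accepted_this_sweep += 1
        sweeps += 1
        trace.append(remaining)
        if accepted_this_sweep == 0:
            break

    unassigned = [
        CandidateEdge(origins[i], w)
        for i in range(len(origins))
        for w in sorted(stacks[i])
    ]
    surrogate = CommuterNetwork(R.origin_level, R.dest_level, surrogate_edges)
    return AssignmentResult(
        surrogate=surrogate,
        unassigned=unassigned,
        trace=trace,
        sweeps=sweeps,
        accepted_count=accepted_count,
        accepted_weight=accepted_weight,
        new_edges=new_edges,
        termination=termination,
    )
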