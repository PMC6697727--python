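import numpy as np
import pytest

from ttwsurrogate import (
    COARSE,
    FINE,
    BudgetLedger,
    CandidateEdge,
    CommuterNetwork,
    ZoneHierarchy,
    aggregate,
    assign_candidates,
    build_allowed_origins,
    initialize_ledger,
    intersect,
    merge_edge,
    missing_edges,
    weight_discrepancies,
)
from ttwsurrogate.assignment import AllowedOrigins


@pytest.fixture
def tiny():
    """One coarse pair (A→D), origins a1/a2, destination d1."""
    h = ZoneHierarchy(origin_parent={"a1": "A", "a2": "A"}, dest_parent={"d1": "D"})
    R = CommuterNetwork(FINE, FINE, {("a2", "d1"): 3})
    gamma = CommuterNetwork(COARSE, FINE, {("A", "d1"): 5})
    return h, R, gamma


def overlap_of(B, A):
    return intersect(B, A)


def test_allowed_origins_hand_case(tiny):
    h, R, gamma = tiny
    B = CommuterNetwork(COARSE, COARSE, {("A", "D"): 8})
    ov = overlap_of(B, aggregate(R, h))
    allowed = build_allowed_origins(gamma, ov, h)
    assert allowed.by_destination == {"d1": frozenset({"a1", "a2"})}


def test_allowed_origins_red_line_case(tiny):
    """Γ edge exists but its coarse pair is outside the overlap -> empty set."""
    h, R, gamma = tiny
    B = CommuterNetwork(COARSE, COARSE, {("Z", "D"): 8})  # no (A, D) edge
    ov = overlap_of(B, aggregate(R, h))
    allowed = build_allowed_origins(gamma, ov, h)
    assert allowed.by_destination == {"d1": frozenset()}


def test_allowed_origins_matches_brute_force():
    rng = np.random.default_rng(8)
    coarse = [f"S{i}" for i in range(6)]
    h = ZoneHierarchy(
        origin_parent={f"x{i}": coarse[i % 6] for i in range(30)},
        dest_parent={f"y{j}": coarse[j % 6] for j in range(18)},
    )
    gamma_edges = {}
    for co in coarse:
        for y in h.dest_parent:
            if rng.random() < 0.3:
                gamma_edges[(co, y)] = int(rng.integers(1, 9))
    gamma = CommuterNetwork(COARSE, FINE, gamma_edges)
    shared = [
        (a, b) for a in coarse for b in coarse if rng.random() < 0.4
    ]
    from ttwsurrogate.network import EdgeOverlap
    ov = EdgeOverlap(sorted(shared), np.ones(len(shared)), np.ones(len(shared)))
    allowed = build_allowed_origins(gamma, ov, h)
    # brute-force triple loop over (gamma, shared pairs, hierarchy)
    for y in {y for (_, y) in gamma_edges}:
        expect = set()
        for (co, yy) in gamma_edges:
            if yy != y:
                continue
            for pair in shared:
                if pair == (co, h.parent_of(y, "dest")):
                    for x in h.origin_parent:
                        if h.parent_of(x, "origin") == co:
                            expect.add(x)
        assert allowed.by_destination[y] == expect


def run_tiny(tiny, budget, capacity):
    h, R, gamma = tiny
    allowed = AllowedOrigins({"d1": frozenset({"a1", "a2"})})
    ledger = BudgetLedger({("A", "D"): budget}, {"d1": capacity})
    return assign_candidates(
        R, [CandidateEdge("a1", 3)], allowed, ledger, h, seed=0
    ), ledger


def test_accept_when_all_constraints_slack(tiny):
    result, ledger = run_tiny(tiny, budget=5, capacity=4)
    assert result.surrogate.edges[("a1", "d1")] == 3
    assert ledger.coarse_budget[("A", "D")] == 2
    assert ledger.dest_capacity["d1"] == 1
    assert result.unassigned == []
    assert result.new_edges == 1


def test_budget_binding_rejects(tiny):
    result, ledger = run_tiny(tiny, budget=2, capacity=99)
    assert result.unassigned == [CandidateEdge("a1", 3)]
    assert ("a1", "d1") not in result.surrogate.edges
    assert ledger.coarse_budget[("A", "D")] == 2


def test_capacity_binding_rejects(tiny):
    result, _ = run_tiny(tiny, budget=99, capacity=2)
    assert result.unassigned == [CandidateEdge("a1", 3)]


def test_merge_edge_semantics():
    edges = {("a1", "d1"): 4}
    assert merge_edge(edges, ("a1", "d1"), 3) is False
    assert edges[("a1", "d1")] == 7
    assert merge_edge(edges, ("a2", "d1"), 3) is True
    assert edges[("a2", "d1")] == 3


def test_ledger_initialization(tiny):
    h, R, gamma = tiny
    B = CommuterNetwork(COARSE, COARSE, {("A", "D"): 8})
    ledger, ov = initialize_ledger(R, B, {"d1": 10}, h)
    assert ledger.coarse_budget == {("A", "D"): 5}   # 8 - aggregate(R)=3
    assert ledger.dest_capacity == {"d1": 7}          # 10 - in-strength(R)=3
    assert ov.shared == [("A", "D")]


def audit(truth, release, result):
    """Hard-constraint audit over a full reconstruction output."""
    h = truth.hierarchy
    R, B, gamma = release.R, release.B, release.gamma
    S = result.surrogate
    A = aggregate(R, h)
    C = aggregate(S, h)
    ov = intersect(B, A)
    shared = set(ov.shared)
    wb = dict(zip(ov.shared, ov.weights_left.tolist()))
    wa = dict(zip(ov.shared, ov.weights_right.tolist()))
    # 1. additions never exceed the initial budget Δw = w_B − w_A on any
    #    coarse edge; wherever the budget was non-negative the aggregated
    #    surrogate stays at or below the trusted coarse weight.  (On edges
    #    where the released products themselves overshoot — w_A > w_B — an
    #    addition-only repair cannot reduce the excess; nothing may be added
    #    there.)
    for e in shared:
        added = C.edges[e] - wa[e]
        assert added >= 0
        assert added <= max(wb[e] - wa[e], 0)
        if wb[e] >= wa[e]:
            assert C.edges[e] <= wb[e]
    # 2. no coarse pair outside E_A (additions confined to the overlap)
    assert set(C.edges) == set(A.edges)
    added = {e: w for e, w in C.edges.items() if w != A.edges.get(e)}
    assert set(added) <= shared
    # 3. mixed-level topology: new pairs only where Γ allows
    mixed_S = aggregate(S, h, "coarse", "fine")
    mixed_R = aggregate(R, h, "coarse", "fine")
    new_pairs = set(mixed_S.edges) - set(mixed_R.edges)
    assert new_pairs <= set(gamma.edges)
    # 4. destination capacities respected
    in_s = S.in_strengths()
    for y, n_y in truth.dest_populations.items():
        assert in_s.get(y, 0) <= n_y
    # 5. exact commuter accounting
    assert S.total_commuters == R.total_commuters + result.assignment.accepted_weight


def test_synthetic_run_passes_audit(small_products):
    from ttwsurrogate import reconstruct

    truth, release = small_products
    res = reconstruct(
        release.R, release.B, release.gamma, truth.hierarchy,
        truth.origin_populations, truth.dest_populations,
        release.H, release.H_populations, seed=3,
    )
    audit(truth, release, res)
    assert res.assignment.accepted_count > 0


def test_determinism_and_trace_monotone(small_products):
    from ttwsurrogate import reconstruct

    truth, release = small_products
    kwargs = dict(
        R=release.R, B=release.B, gamma=release.gamma, hierarchy=truth.hierarchy,
        origin_populations=truth.origin_populations,
        dest_populations=truth.dest_populations,
        reference=release.H, reference_populations=release.H_populations,
    )
    r1 = reconstruct(seed=9, **kwargs)
    r2 = reconstruct(seed=9, **kwargs)
    assert r1.surrogate.edges == r2.surrogate.edges
    assert r1.assignment.trace == r2.assignment.trace
    trace = r1.assignment.trace
    assert all(a >= b for a, b in zip(trace, trace[1:]))
    assert r1.assignment.termination == "converged"
    # last sweep accepted nothing: plateau reached
    assert trace[-1] == trace[-2]
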