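"""End-to-end reconstruction: fit, candidate generation, assignment, metrics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np

from .assignment import (
    AssignmentResult,
    build_allowed_origins,
    assign_candidates,
    initialize_ledger,
)
from .candidates import CandidateSet, OriginDeficit, compute_deficits, generate_candidates
from .geography import ZoneHierarchy
from .network import COARSE, CommuterNetwork, aggregate
from .validation import validation_report
from .weights import ConditionalWeightDistribution, fit_conditional


@dataclass
class ReconstructionResult:
    """Everything a reconstruction run produced."""

    surrogate: CommuterNetwork            # S = R plus accepted candidate edges
    aggregated_input: CommuterNetwork     # A = aggregate(R)
    aggregated_surrogate: CommuterNetwork # C = aggregate(S)
    distribution: ConditionalWeightDistribution
    deficits: List[OriginDeficit]
    candidates: CandidateSet
    assignment: AssignmentResult

    def report(self, B: CommuterNetwork) -> Dict[str, object]:
        """Validation metrics of the (A, B, C) triple plus run counters."""
        out = validation_report(self.aggregated_input, B, self.aggregated_surrogate)
        out["run"] = {
            "candidates": len(self.candidates),
            "candidate_commuters": self.candidates.total_weight,
            "accepted": self.assignment.accepted_count,
            "accepted_commuters": self.assignment.accepted_weight,
            "new_edges": self.assignment.new_edges,
            "unassigned": len(self.assignment.unassigned),
            "unassigned_commuters": self.assignment.unassigned_weight,
            "sweeps": self.assignment.sweeps,
            "termination": self.assignment.termination,
        }
        return out


def _stage_seeds(seed: int, n: int = 2) -> List[int]:
    """Independent per-stage integer seeds derived from the master seed."""
    children = np.random.SeedSequence(int(seed)).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def reconstruct(
    R: CommuterNetwork,
    B: CommuterNetwork,
    gamma: CommuterNetwork,
    hierarchy: ZoneHierarchy,
    origin_populations: Mapping[str, int],
    dest_populations: Mapping[str, int],
    reference: CommuterNetwork,
    reference_populations: Mapping[str, int],
    seed: int,
    w_min: int = 3,
    n_bins: int = 20,
    binning: str = "quantile",
    max_attempts: int = 1000,
    max_sweeps: int = 1_000_000,
    time_budget: Optional[float] = None,
    distribution: Optional[ConditionalWeightDistribution] = None,
) -> ReconstructionResult:
    """Run the full surrogate reconstruction.

    Stages: fit P(w | N_x) on the reference release; compute per-origin
    worker deficits of R against ``origin_populations``; sample candidate
    edges; assign them to destinations under the Γ / overlap topology, the
    coarse-edge budgets of B, and the destination capacities
    ``dest_populations``; aggregate the surrogate for comparison.  A
    pre-fitted ``distribution`` may be passed to skip the fitting stage.
    """
    cand_seed, assign_seed = _stage_seeds(seed)
    dist = distribution if distribution is not None else fit_conditional(
        reference, reference_populations, n_bins=n_bins, strategy=binning, w_min=w_min
    )
    deficits = compute_deficits(R, origin_populations)
    cand = generate_candidates(deficits, dist, seed=cand_seed, max_attempts=max_attempts)
    A = aggregate(R, hierarchy, COARSE, COARSE)
    ledger, overlap = initialize_ledger(
        R, B, dict(dest_populations), hierarchy, aggregated=A
    )
    allowed = build_allowed_origins(gamma, overlap, hierarchy)
    result = assign_candidates(
        R, cand.candidates, allowed, ledger, hierarchy,
        seed=assign_seed, max_sweeps=max_sweeps, time_budget=time_budget,
    )
    C = aggregate(result.surrogate, hierarchy, COARSE, COARSE)
    return ReconstructionResult(
        surrogate=result.surrogate,
        aggregated_input=A,
        aggregated_surrogate=C,
        distribution=dist,
        deficits=deficits,
        candidates=cand,
        assignment=result,
    )
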