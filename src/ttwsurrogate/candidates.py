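"""Candidate out-edge generation: accounting for each origin's missing workers.

For each fine origin x the deficit ΔN_x = N_x − N_x^R is the gap between the
worker population reported for the zone and the out-strength the perturbed
fine network R actually accounts for.  Candidate edges (x, w′) are sampled
from the population-conditional weight distribution until the residual
deficit falls below the minimum released edge size w_min, so the candidate
set accounts for (almost) precisely the missing workers of every origin
while preserving a realistic weight distribution.

A sampled weight larger than the remaining residual is rejected and redrawn;
after ``max_attempts`` consecutive rejections the origin is closed and
flagged as capped (a degenerate pmf whose smallest supported weight exceeds
the residual would otherwise loop forever).  Origins whose deficit is
negative (perturbation overshoot) or below w_min yield no candidates —
commuters are only ever added, never removed.

Each origin draws from its own RNG substream derived from the master seed
and a stable hash of the origin code, so candidate generation is independent
of iteration order and reproducible under parallel or reordered execution.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Sequence, Set

import numpy as np
import pandas as pd

from .network import CommuterNetwork
from .weights import ConditionalWeightDistribution


class CandidateEdge(NamedTuple):
    origin: str
    weight: int


@dataclass(frozen=True)
class OriginDeficit:
    """Worker-population bookkeeping for one fine origin."""

    origin: str
    known_workers: int     # N_x from the independent population table
    accounted: int         # N_x^R, out-strength of the origin in R
    deficit: int           # ΔN_x = N_x − N_x^R; may be ≤ 0

    def __post_init__(self) -> None:
        if self.deficit != self.known_workers - self.accounted:
            raise ValueError("deficit must equal known_workers - accounted")


def compute_deficits(
    R: CommuterNetwork, populations: Mapping[str, int]
) -> List[OriginDeficit]:
    """One deficit record per origin in the population table.

    Origins present in the populations but absent from R get accounted = 0;
    records are returned in canonical (sorted origin) order.
    """
    strengths = R.out_strengths()
    records = []
    for origin in sorted(populations):
        n_x = int(populations[origin])
        acc = int(strengths.get(origin, 0))
        records.append(OriginDeficit(origin, n_x, acc, n_x - acc))
    return records


@dataclass
class CandidateSet:
    """Output of :func:`generate_candidates`."""

    candidates: List[CandidateEdge]
    residuals: Dict[str, int]       # residual deficit per positive-deficit origin
    capped: Set[str] = field(default_factory=set)

    @property
    def total_weight(self) -> int:
        return sum(c.weight for c in self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.candidates, columns=["origin", "weight"])


def _origin_rng(master_seed: int, origin: str) -> np.random.Generator:
    digest = hashlib.blake2b(origin.encode("utf-8"), digest_size=4).digest()
    sub = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                  int.from_bytes(digest, "big")])
    return np.random.Generator(np.random.PCG64(sub))


def generate_candidates(
    deficits: Sequence[OriginDeficit],
    dist: ConditionalWeightDistribution,
    seed: int,
    max_attempts: int = 1000,
) -> CandidateSet:
    """Sample the candidate edge set M = {(x, w′)} from P(w | N_x).

    Per origin, draws are accepted while w′ does not exceed the residual
    deficit (a weight equal to the residual is accepted), and sampling stops
    once the residual drops below ``dist.w_min`` — candidates account for the
    missing workers of each origin to within w_min.
    """
    w_min = dist.w_min
    out: List[CandidateEdge] = []
    residuals: Dict[str, int] = {}
    capped: Set[str] = set()
    for record in sorted(deficits, key=lambda r: r.origin):
        if record.deficit < w_min:
            continue
        rng = _origin_rng(seed, record.origin)
        residual = record.deficit
        rejects = 0
        while residual >= w_min:
            w = dist.sample(record.known_workers, rng)
            if w <= residual:
                out.append(CandidateEdge(record.origin, w))
                residual -= w
                rejects = 0
            else:
                rejects += 1
                if rejects >= max_attempts:
                    capped.add(record.origin)
                    break
        residuals[record.origin] = residual
    return CandidateSet(out, residuals, capped)
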