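"""Synthetic census products: ground truth plus perturbed releases.

The generator builds a complete, internally consistent stand-in for the
census input ecosystem so the whole reconstruction is testable end to end
and its recovery can be scored against a known truth:

* a two-level zone system — coarse zones, each containing a fixed number of
  fine origins and a heterogeneous number of fine destinations — laid out on
  a latent 2D plane;
* a ground-truth fine network T from a gravity model: each origin's workers
  are distributed over destinations with probability proportional to a
  heavy-tailed destination attractiveness times an exponential
  distance-decay kernel, so a few hub destinations absorb a disproportionate
  share of the in-strength (mimicking central-business-district employment);
* perturbed releases emulating a disclosure-control protocol without
  additivity: the fine release R censors weights below w_min, suppresses
  surviving edges with probability decaying exponentially in the weight, and
  adds small symmetric integer noise; the coarse release B and the
  mixed-partition release Γ are aggregates of T with binomial thinning plus
  small noise, calibrated to mild total-commuter losses (≈6% and ≈8%) so
  the loss staircase of the real data — fine ≫ mixed > coarse — is
  reproduced;
* a reference fine release H from an independent redraw of the same gravity
  model (same zones, worker counts and kernel, fresh randomness), censored
  at w_min only — honouring the method's assumption that the
  population-conditional weight structure is stable across census years;
* worker-population tables N_X and N_Y equal to T's out- and in-strengths
  exactly (populations come from separate, unperturbed tabulations and are
  treated as constraints, not targets of repair).

All randomness is driven by a single seed; distinct substreams per product
keep every release reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np

from .geography import ZoneHierarchy
from .network import COARSE, FINE, CommuterNetwork, aggregate


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for the synthetic census.

    Defaults are desk-scale: ~400 fine origins, ~2×10⁵ commuters, full
    pipeline in minutes on one CPU.  Perturbation rates are calibrated so
    the realized total-commuter losses sit near the reference conditions:
    roughly a third of commuters lost from the fine release, ≈6% from the
    coarse release B and ≈8% from the mixed release Γ.
    """

    n_coarse: int = 40
    origins_per_coarse: int = 10
    dest_min: int = 2
    dest_max: int = 15
    mean_workers: float = 500.0      # mean workers per fine origin (lognormal)
    worker_sigma: float = 0.6        # lognormal sigma of origin worker counts
    attract_sigma: float = 1.3       # lognormal sigma of destination attractiveness
    decay_length: float = 0.25       # gravity distance-decay scale (unit square)
    scatter: float = 0.05            # fine-zone scatter around the coarse centre
    w_min: int = 3                   # smallest released edge weight
    p_drop: float = 0.60             # suppression probability at w = w_min
    drop_decay: float = 0.45         # exponential decay rate of suppression in w
    fine_noise: int = 1              # ± amplitude of integer noise on fine release
    b_loss: float = 0.059            # binomial thinning rate for coarse release B
    gamma_loss: float = 0.060        # binomial thinning rate for mixed release Γ
    coarse_noise: int = 1            # ± amplitude of integer noise on B and Γ

    def __post_init__(self) -> None:
        for name in ("p_drop", "b_loss", "gamma_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dest_min < 1 or self.dest_max < self.dest_min:
            raise ValueError("destination count range is invalid")
        if self.w_min < 1:
            raise ValueError("w_min must be >= 1")

    @classmethod
    def zero_perturbation(cls, **overrides) -> "SyntheticScenario":
        """Identity limit: every release equals (an aggregate of) the truth."""
        params = dict(
            w_min=1, p_drop=0.0, drop_decay=0.0, fine_noise=0,
            b_loss=0.0, gamma_loss=0.0, coarse_noise=0,
        )
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> Dict[str, object]:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth T and everything consistent with it by construction."""

    network: CommuterNetwork             # fine origin → fine destination
    hierarchy: ZoneHierarchy
    origin_populations: Dict[str, int]   # N_X == out-strengths of T
    dest_populations: Dict[str, int]     # N_Y == in-strengths of T (0 allowed)
    # private state needed to redraw an independent reference release
    _origin_codes: List[str] = field(repr=False, default_factory=list)
    _dest_codes: List[str] = field(repr=False, default_factory=list)
    _workers: np.ndarray = field(repr=False, default=None)
    _probs: np.ndarray = field(repr=False, default=None)


@dataclass
class SyntheticRelease:
    """The perturbed products derived from one truth."""

    R: CommuterNetwork                   # fine release (heavily perturbed)
    B: CommuterNetwork                   # coarse release (mildly perturbed)
    gamma: CommuterNetwork               # mixed coarse-origin → fine-dest release
    H: CommuterNetwork                   # independent reference fine release
    H_populations: Dict[str, int]        # origin populations for fitting on H
    losses: Dict[str, float]             # realized total-commuter loss fractions


def _draw_counts(
    workers: np.ndarray, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial split of each origin's workers over destinations."""
    return rng.multinomial(workers, probs)


def generate_truth(scenario: SyntheticScenario, seed: int) -> SyntheticTruth:
    """Draw the ground-truth fine network and its consistent side tables."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 0])))
    s = scenario

    centers = rng.random((s.n_coarse, 2))
    coarse_codes = [f"sa2_{c:03d}" for c in range(s.n_coarse)]

    origin_codes: List[str] = []
    origin_parent: Dict[str, str] = {}
    origin_pos: List[np.ndarray] = []
    for c in range(s.n_coarse):
        for k in range(s.origins_per_coarse):
            code = f"sa1_{c:03d}_{k:02d}"
            origin_codes.append(code)
            origin_parent[code] = coarse_codes[c]
            origin_pos.append(centers[c] + rng.normal(0.0, s.scatter, 2))

    dest_codes: List[str] = []
    dest_parent: Dict[str, str] = {}
    dest_pos: List[np.ndarray] = []
    n_dest_per_coarse = rng.integers(s.dest_min, s.dest_max + 1, size=s.n_coarse)
    for c in range(s.n_coarse):
        for k in range(int(n_dest_per_coarse[c])):
            code = f"dzn_{c:03d}_{k:02d}"
            dest_codes.append(code)
            dest_parent[code] = coarse_codes[c]
            dest_pos.append(centers[c] + rng.normal(0.0, s.scatter, 2))

    mu = np.log(s.mean_workers) - 0.5 * s.worker_sigma**2
    workers = np.maximum(
        1, np.round(rng.lognormal(mu, s.worker_sigma, len(origin_codes)))
    ).astype(np.int64)

    attract = rng.lognormal(0.0, s.attract_sigma, len(dest_codes))
    op = np.asarray(origin_pos)
    dp = np.asarray(dest_pos)
    dist = np.linalg.norm(op[:, None, :] - dp[None, :, :], axis=2)
    probs = attract[None, :] * np.exp(-dist / s.decay_length)
    probs /= probs.sum(axis=1, keepdims=True)

    counts = _draw_counts(workers, probs, rng)
    edges = {
        (origin_codes[i], dest_codes[j]): int(counts[i, j])
        for i, j in zip(*np.nonzero(counts))
    }
    network = CommuterNetwork(FINE, FINE, edges)
    hierarchy = ZoneHierarchy(origin_parent, dest_parent)
    n_x = {origin_codes[i]: int(workers[i]) for i in range(len(origin_codes))}
    in_strength = counts.sum(axis=0)
    n_y = {dest_codes[j]: int(in_strength[j]) for j in range(len(dest_codes))}
    return SyntheticTruth(
        network=network,
        hierarchy=hierarchy,
        origin_populations=n_x,
        dest_populations=n_y,
        _origin_codes=origin_codes,
        _dest_codes=dest_codes,
        _workers=workers,
        _probs=probs,
    )


def _perturb_fine(
    T: CommuterNetwork, s: SyntheticScenario, rng: np.random.Generator
) -> CommuterNetwork:
    """Censor, suppress (exponentially decaying in w), and jitter the fine truth."""
    out: Dict[Tuple[str, str], int] = {}
    for key, w in T.sorted_edges():
        if w < s.w_min:
            continue
        if s.p_drop > 0 and rng.random() < s.p_drop * np.exp(
            -s.drop_decay * (w - s.w_min)
        ):
            continue
        if s.fine_noise:
            w = int(w) + int(rng.integers(-s.fine_noise, s.fine_noise + 1))
            w = max(w, s.w_min)
        out[key] = int(w)
    return CommuterNetwork(T.origin_level, T.dest_level, out)


def _perturb_coarse(
    agg: CommuterNetwork, loss: float, noise: int, w_min: int,
    rng: np.random.Generator,
) -> CommuterNetwork:
    """Binomial thinning plus small symmetric noise; censored at w_min."""
    out: Dict[Tuple[str, str], int] = {}
    for key, w in agg.sorted_edges():
        kept = int(rng.binomial(w, 1.0 - loss)) if loss > 0 else int(w)
        if noise:
            kept += int(rng.integers(-noise, noise + 1))
        if kept >= w_min:
            out[key] = kept
    return CommuterNetwork(agg.origin_level, agg.dest_level, out)


def perturb_release(
    truth: SyntheticTruth, scenario: SyntheticScenario, seed: int
) -> SyntheticRelease:
    """Derive the released products (R, B, Γ, H) from one truth draw."""
    s = scenario
    streams = [
        np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), k])))
        for k in (1, 2, 3, 4)
    ]
    rng_r, rng_b, rng_g, rng_h = streams
    T = truth.network
    hierarchy = truth.hierarchy

    R = _perturb_fine(T, s, rng_r)
    B = _perturb_coarse(
        aggregate(T, hierarchy, COARSE, COARSE), s.b_loss, s.coarse_noise, s.w_min, rng_b
    )
    gamma = _perturb_coarse(
        aggregate(T, hierarchy, COARSE, FINE), s.gamma_loss, s.coarse_noise, s.w_min,
        rng_g,
    )

    # Independent reference release: same zones, worker counts and gravity
    # kernel, fresh multinomial draw, censored at w_min only.
    counts = _draw_counts(truth._workers, truth._probs, rng_h)
    h_edges = {
        (truth._origin_codes[i], truth._dest_codes[j]): int(counts[i, j])
        for i, j in zip(*np.nonzero(counts >= s.w_min))
    }
    H = CommuterNetwork(FINE, FINE, h_edges)

    n_t = T.total_commuters
    losses = {
        "R": 1.0 - R.total_commuters / n_t,
        "B": 1.0 - B.total_commuters / n_t,
        "gamma": 1.0 - gamma.total_commuters / n_t,
        "H": 1.0 - H.total_commuters / n_t,
    }
    return SyntheticRelease(
        R=R, B=B, gamma=gamma, H=H,
        H_populations=dict(truth.origin_populations),
        losses=losses,
    )


def generate_products(
    scenario: SyntheticScenario, seed: int
) -> Tuple[SyntheticTruth, SyntheticRelease]:
    """Convenience: one truth draw plus its perturbed releases."""
    truth = generate_truth(scenario, seed)
    release = perturb_release(truth, scenario, seed)
    return truth, release
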