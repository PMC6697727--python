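"""Population-conditional edge-weight distributions P(w | N_x).

The reconstruction re-samples the weights of missing out-edges from the
empirical distribution of edge weights conditioned on the origin zone's
worker population, estimated from a reference fine network (a census year
released under the additivity-preserving protocol, whose aggregation
behaviour is trusted).  The key modelling assumption is that this
relationship between local population and out-edge weight distribution is
stable across census years, so a distribution fitted on the reference year
can be sampled for the target year.  The fit therefore never mixes
target-year edges into the reference.

Origin populations are binned (quantile bins by default, so per-bin support
stays balanced under heavily skewed population distributions) and one
empirical pmf over integer weights w ≥ w_min is kept per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping

import numpy as np
import pandas as pd

from .network import CommuterNetwork

DEFAULT_W_MIN = 3


@dataclass
class ConditionalWeightDistribution:
    """Binned empirical pmf over integer edge weights, conditional on N_x.

    Attributes
    ----------
    bin_edges
        Monotone array of length ``n_bins + 1`` over origin worker
        populations; bin i covers ``[bin_edges[i], bin_edges[i+1])`` with the
        last bin closed on the right.
    support, probs
        Per-bin sorted integer weight values and their probabilities.
    bin_counts
        Number of reference edges that landed in each bin (0 marks an empty
        bin).
    w_min
        Smallest released edge weight; every supported weight is ≥ w_min.
    """

    bin_edges: np.ndarray
    support: List[np.ndarray]
    probs: List[np.ndarray]
    bin_counts: np.ndarray
    w_min: int = DEFAULT_W_MIN
    _centers: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=np.int64)
        n_bins = len(self.bin_edges) - 1
        if not (len(self.support) == len(self.probs) == n_bins == len(self.bin_counts)):
            raise ValueError("inconsistent bin structure")
        if not self.bin_counts.any():
            raise ValueError("no nonempty population bin: nothing to sample from")
        for i in range(n_bins):
            self.support[i] = np.asarray(self.support[i], dtype=np.int64)
            self.probs[i] = np.asarray(self.probs[i], dtype=float)
            if self.bin_counts[i]:
                if abs(self.probs[i].sum() - 1.0) > 1e-12:
                    raise ValueError(f"bin {i}: pmf does not sum to 1")
                if (self.support[i] < self.w_min).any():
                    raise ValueError(f"bin {i}: supported weight below w_min={self.w_min}")
        self._centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def empty_bins(self) -> np.ndarray:
        """Indices of bins with no reference support."""
        return np.flatnonzero(self.bin_counts == 0)

    def bin_for(self, population: float) -> int:
        """Bin index whose pmf is sampled for an origin of this population.

        Out-of-range populations are clipped into the covered range; if the
        resulting bin is empty, the nearest nonempty bin by bin-centre
        distance is used, ties resolved toward the lower bin.
        """
        idx = int(np.searchsorted(self.bin_edges, population, side="right")) - 1
        idx = min(max(idx, 0), self.n_bins - 1)
        if self.bin_counts[idx] > 0:
            return idx
        nonempty = np.flatnonzero(self.bin_counts > 0)
        dist = np.abs(self._centers[nonempty] - self._centers[idx])
        return int(nonempty[np.argmin(dist)])  # argmin takes first (lower) on ties

    def sample(self, population: float, rng: np.random.Generator) -> int:
        """Draw one integer weight w′ from the pmf of the bin for ``population``."""
        i = self.bin_for(population)
        return int(rng.choice(self.support[i], p=self.probs[i]))

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Flatten to a (bin_lo, bin_hi, weight, probability, count) table.

        Empty bins emit no rows; reconstructing from the frame therefore
        merges empty bins away (the sampling fallback already skips them).
        """
        rows = []
        for i in range(self.n_bins):
            if not self.bin_counts[i]:
                continue
            for w, p in zip(self.support[i], self.probs[i]):
                rows.append(
                    (self.bin_edges[i], self.bin_edges[i + 1], int(w), float(p),
                     int(self.bin_counts[i]))
                )
        return pd.DataFrame(
            rows, columns=["bin_lo", "bin_hi", "weight", "probability", "bin_count"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, w_min: int = DEFAULT_W_MIN
                   ) -> "ConditionalWeightDistribution":
        bins = sorted({(lo, hi) for lo, hi in zip(frame["bin_lo"], frame["bin_hi"])})
        edges = np.array([b[0] for b in bins] + [bins[-1][1]], dtype=float)
        support, probs, counts = [], [], []
        for lo, hi in bins:
            sub = frame[(frame["bin_lo"] == lo) & (frame["bin_hi"] == hi)]
            sub = sub.sort_values("weight")
            support.append(sub["weight"].to_numpy(dtype=np.int64))
            probs.append(sub["probability"].to_numpy(dtype=float))
            counts.append(int(sub["bin_count"].iloc[0]))
        return cls(edges, support, probs, np.array(counts), w_min=w_min)


def fit_conditional(
    reference: CommuterNetwork,
    populations: Mapping[str, int],
    n_bins: int = 20,
    strategy: str = "quantile",
    w_min: int = DEFAULT_W_MIN,
) -> ConditionalWeightDistribution:
    """Estimate P(w | N_x) from a reference fine network.

    Parameters
    ----------
    reference
        Fine origin→destination network from the trusted reference year,
        assumed already censored at ``w_min`` (no smaller weights present).
    populations
        Worker population N_x per origin of the reference network.
    n_bins, strategy
        Number of population bins and binning rule: ``"quantile"`` (default;
        quantiles of the per-edge population values, so bins are balanced by
        out-edge support) or ``"fixed"`` (equal width over the observed
        population range).
    """
    if reference.n_edges == 0:
        raise ValueError("reference network has no edges")
    missing = sorted({x for (x, _) in reference.edges} - set(populations))
    if missing:
        raise ValueError(
            f"{len(missing)} reference origins lack a population entry: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )

    pops = np.empty(reference.n_edges, dtype=float)
    ws = np.empty(reference.n_edges, dtype=np.int64)
    for k, ((x, _), w) in enumerate(reference.sorted_edges()):
        pops[k] = populations[x]
        ws[k] = w
    if (ws < w_min).any():
        raise ValueError(
            f"reference network contains weights below w_min={w_min}; "
            "censor it first or lower w_min"
        )

    if strategy == "quantile":
        edges = np.quantile(pops, np.linspace(0.0, 1.0, n_bins + 1))
        edges = np.unique(edges)
        if len(edges) < 2:  # all populations identical
            edges = np.array([edges[0], edges[0] + 1.0])
    elif strategy == "fixed":
        lo, hi = pops.min(), pops.max()
        if hi == lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        raise ValueError(f"unknown binning strategy {strategy!r}")

    idx = np.searchsorted(edges, pops, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)  # max population closes the last bin

    support: List[np.ndarray] = []
    probs: List[np.ndarray] = []
    counts: List[int] = []
    for i in range(len(edges) - 1):
        w_bin = ws[idx == i]
        if w_bin.size == 0:
            support.append(np.empty(0, dtype=np.int64))
            probs.append(np.empty(0, dtype=float))
            counts.append(0)
            continue
        values, freq = np.unique(w_bin, return_counts=True)
        support.append(values)
        probs.append(freq / freq.sum())
        counts.append(int(w_bin.size))
    return ConditionalWeightDistribution(
        edges, support, probs, np.array(counts), w_min=w_min
    )


def sample_weight(
    dist: ConditionalWeightDistribution, population: float, rng: np.random.Generator
) -> int:
    """Draw one weight with probability P(w | N_x) for ``population``."""
    return dist.sample(population, rng)
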