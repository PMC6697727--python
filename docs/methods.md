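# Methods

## Data model

A commuter network is a weighted bipartite graph between origin (usual
residence) zones and destination (place of work) zones at a declared
partition level per side, `fine` or `coarse`. Fine zones nest exactly inside
coarse zones on both sides (an exact cover), so amalgamation of counts from
fine to coarse is unambiguous. Weights are commuter counts: positive
integers, with "edge exists" ⇔ "key present", and every aggregation,
overlap and discrepancy operation is exact integer arithmetic. Zone codes
are opaque strings; coarse origin and coarse destination codes may share a
code space but are always addressed through an explicit side argument.
Serialisation uses a canonical lexicographic edge order, so a fixed seed
reproduces output files byte for byte.

## Reconstruction procedure

**Inputs.** The perturbed fine release `R`; the coarse release `B` (treated
as quantitative ground truth); the mixed coarse-origin → fine-destination
release `Γ` (topological constraint); a reference fine network `H` with its
origin worker populations; target-period worker populations `N_X` (origins)
and `N_Y` (destinations). Populations come from separate tabulations and
are treated as constraints, never as targets of repair.

**Stage 1 — conditional weight model.** `P(w | N_x)` is the empirical pmf of
out-edge weights, binned by origin worker population. Defaults: 20 quantile
bins over the per-edge population values (balanced support under skewed
population distributions; equal-width bins are selectable) and
`w_min = 3`, the smallest released edge weight — the reference network is
expected to be censored there already and the fit rejects smaller weights.
Sampling for a population outside every nonempty bin falls back to the
nearest nonempty bin by bin-centre distance, ties to the lower bin,
preserving the monotone population → weight-tail trend. The assumption
underlying the whole stage is that this population-conditional weight
structure is stable between the reference and target periods; the fit never
mixes target-period edges into the reference.

**Stage 2 — candidate generation.** Per-origin deficits
`ΔN_x = N_x − Σ_y w(x, y; R)` may be negative (perturbation overshoot);
such origins, and origins with `ΔN_x < w_min`, produce no candidates —
commuters are only ever added. For the rest, weights are sampled from
`P(w | N_x)`; a draw is accepted when it does not exceed the remaining
residual (a draw equal to the residual is accepted) and sampling stops when
the residual drops below `w_min`, so each origin's candidates account for
its missing workers to within `w_min`. A draw cap (default 1000 consecutive
rejections) closes origins whose bin's smallest supported weight exceeds
the residual, which would otherwise loop forever; capped origins are
reported. Each origin uses an RNG substream keyed by the master seed and a
stable hash of its code, making the candidate set independent of iteration
order.

**Stage 3 — constrained assignment.** The surrogate starts as a copy of
`R`. For destination `y`, the compatible origins are the fine children of
coarse origins `Φ` such that `(Φ, y) ∈ Γ` and `(Φ, parent(y)) ∈ E_AB`,
where `E_AB = E_B ∩ E_A` and `A = aggregate(R)`. Each sweep visits every
destination once in a fresh uniform random permutation; one compatible
candidate is drawn uniformly and accepted iff its weight fits both the
remaining coarse budget (initially `Δw = w_B − w_A`; non-positive budgets
never accept) and the remaining destination capacity (initially `N_y`
minus `R`'s in-strength at `y`, since the surrogate starts as `R`).
Accepted candidates leave the pool and merge into the surrogate (summing
with an existing edge if the pair is already present; only genuinely new
keys count as new edges); rejected candidates remain and may be retried at
other destinations or later sweeps. The run terminates when a full sweep
accepts nothing (an optional sweep cap exists for defensive use). Since the
pool only shrinks, the per-sweep unassigned-commuter trace is
non-increasing and converges to a plateau, normally nonzero: candidates too
large for every remaining budget, and commuters on coarse edges missing
from `E_AB` entirely, are unassignable by design. Candidates are never
split into smaller ones.

Two readings of the source algorithms were settled as follows: the
candidate-stage loop guard follows the prose rule (continue while the
residual is at least `w_min`, accept a weight equal to the residual), and
the assignment acceptance test uses the budget semantics (the addition must
*not* exceed the remaining budget). Assignments are deterministic for a
fixed seed; the pipeline derives independent per-stage seeds from one
master seed.

## Validation metrics

All comparisons treat a coarse network as a unipartite weighted graph with
origin and destination code spaces identified. The 2D correlation is the
standard Pearson product-moment correlation over all cells of dense
adjacency matrices on a shared node ordering (undefined — reported as NaN —
if either matrix is constant). The overlap MSE is the mean squared weight
difference over `E_AB` only. Weighted clustering is the Onnela
geometric-mean form, `C_i = (2 / k_i(k_i−1)) Σ_{j<k} (ŵ_ij ŵ_jk ŵ_ki)^{1/3}`
with weights scaled by the global maximum, averaged over all nodes (degree
< 2 contributes 0); opposite-direction weights are summed and self-loops
excluded. Average shortest path applies Dijkstra with edge weight as
inverse distance over the directed edge set (symmetrisation selectable);
unreachable ordered pairs are excluded from the mean and counted in the
report rather than assigned infinity. Clustering and Dijkstra are delegated
to networkx; the test suite checks every metric against independent
brute-force enumerations at 1e-12.

## Synthetic census generator

The generator emulates the input ecosystem, not any agency's actual
(undisclosed) algorithm. Zones: 40 coarse zones at uniform random positions
on the unit square, 10 fine origins and 2–15 fine destinations each,
scattered σ = 0.05 around their centre. Origin worker counts are lognormal
with mean 500 and σ = 0.6 (Σw ≈ 2×10⁵ total commuters, desk scale); worker
counts at that scale keep the full pipeline under a few seconds, and the
test suite and acceptance script use these defaults throughout. Each
origin's workers are split by a multinomial over destinations with
probability ∝ (lognormal attractiveness, σ = 1.3) × exp(−d/0.25), so a few
hub destinations absorb a disproportionate in-strength share, as
central-business-district employment does. `N_X` and `N_Y` equal the
truth's marginals exactly.

Perturbed releases, each from its own seed substream:

* `R` (fine): weights below `w_min = 3` censored; surviving edges
  suppressed with probability `p₀·exp(−λ(w − w_min))`, `p₀ = 0.60`,
  `λ = 0.45`; symmetric integer noise ±1, floored at `w_min`.
* `B` (coarse) and `Γ` (mixed): aggregates of the truth with binomial
  thinning (rates 0.059 and 0.060), noise ±1, censored at `w_min`.
* `H` (reference): an independent multinomial redraw with the same zones,
  worker counts and gravity kernel, censored at `w_min` only — the
  cross-period invariance assumption holds exactly in the generator.

The suppression/thinning rates were calibrated once against the realized
total-commuter losses so the default conditions reproduce the loss
staircase of real perturbed census products — ≈34% of commuters lost from
the fine release, ≈8% from the mixed release, ≈6% from the coarse release —
and were not revisited afterwards. A `zero_perturbation()` scenario
(censoring threshold 1, all rates and noise zero) gives the identity limit
in which every release equals (an aggregate of) the truth and the
reconstruction is a no-op.

What the generator does *not* emulate: spatial autocorrelation beyond the
distance kernel, multi-level partition hierarchies deeper than two, origin-
and destination-side population change between periods (H shares the
truth's worker counts exactly), and any dependence of the perturbation on
cross-tabulation risk. Passing tests therefore demonstrate the mechanics
and constraint-correctness of the method under realistic magnitudes, not
calibration to any particular country's protocol.

## Numerical and degenerate-input choices

Integer arithmetic end to end for network weights, budgets and capacities;
the only floats are probabilities and metric outputs. Empty networks,
empty overlaps and constant adjacency matrices raise or report rather than
guess (empty overlap → error for MSE; zero variance → NaN correlation).
Quantile bin edges are deduplicated, so heavily tied populations produce
fewer, wider bins; a single-valued population range degenerates to one bin.
Destinations absent from `N_Y` have capacity 0 and never accept. A
destination whose compatible candidate pool is empty is skipped without
consuming randomness for it beyond the availability check.

## Known limitations

Coarse edges present in `B` but absent from `A` are outside the overlap and
receive no repair — the commuters they carry are unrecoverable by this
addition-only procedure, exactly as in the source method. Individual coarse
edges where the perturbed inputs overshoot (`w_A > w_B`) cannot be reduced;
no additions occur there. The one-candidate-per-destination-per-sweep
schedule trades speed for fidelity to the source procedure; it converges in
~100–150 sweeps at desk scale but is not optimised for national-scale runs
(where the original took a ~100-hour budget; the sweep and wall-clock caps
exist for that regime).
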