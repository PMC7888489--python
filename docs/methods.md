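# Methods

## Model

Spins `s_i ∈ {−1, +1}` sit on the nodes of a weighted, undirected,
nonnegative connectivity matrix `J` and evolve under single-spin-flip
Glauber dynamics for the ferromagnetic Hamiltonian
`H = −½ Σ_ij J_ij s_i s_j`. A proposed flip of spin `i` changes the energy
by `ΔE_i = 2 s_i Σ_j J_ij s_j` and is accepted with probability
`1/(1 + exp(β ΔE_i))`; this satisfies detailed balance, so the chain samples
the Boltzmann distribution at inverse temperature β (verified in the tests
against the closed-form two-spin partition function).

One *sweep* updates every spin exactly once, in a fresh seeded random
permutation; random order avoids the artifacts of a fixed scan order while
keeping the per-sweep update count fixed. Time series record one
configuration per sweep, so the recorded process is a Markov chain whose
kernel is the permutation-averaged composition of single-site updates —
which is also how the exact small-system oracle in the tests is built.

An adiabatic temperature sweep relaxes at the smallest β (default 1e5
sweeps), then walks an increasing β grid, each point continuing from the
previous point's final configuration, discarding a transient (default 1e4
sweeps) and collecting statistics (default 1e6 sweeps), independently for
each of the default 20 runs. A scaled-down `desk` preset (20 β points,
3 runs, 2e4 collection sweeps) exists for interactive work and is what the
examples, the test suite and the acceptance script use; all problem sizes
below are package choices made so the full pipeline runs in minutes on one
CPU at useful statistical precision.

**Susceptibility.** `χ = N β (⟨m²⟩ − ⟨|m|⟩²)` with `m(t)` the mean spin per
sweep. Using `⟨|m|⟩` rather than `⟨m⟩` handles the finite-size symmetry of
the ordered phase and gives a well-defined peak; the grid argmax of the
across-run mean defines the critical β. For cohort work the peak is refined
by a parabolic fit through the three bracketing grid points
(`interpolated_critical_beta`): when many systems are compared on a common
grid, the grid-snapped argmax imprints the discretization on downstream
statistics as a spurious shared trend.

**Weight normalization.** Raw streamline-count weights put the transition at
a tiny β. The default rescales `J` by the mean node strength, which places
the critical β near 1 for any edge density; dividing by the mean positive
edge weight (an alternative mode) leaves β_c ~ 1/⟨degree⟩ on dense graphs.
Normalization only reparametrizes the β axis; the `none` mode is available
and is what the lattice validation uses.

## Information decomposition

Transfer entropy from one or two source spins to a target is the
conditional mutual information `I(s̃_i ; sources | s_i)` in bits, with the
target's own history conditioned at lag 1 (the dynamics are Markov per
sweep, so one step of history is the natural choice). All distributions are
plugin estimates — configuration frequencies read directly off the series,
with counts pooled across runs before normalizing, `0 log 0 ≡ 0`. No bias
correction is applied; the tests instead budget for the known plugin bias
`(cells − 1)/(2 T ln 2)` where it matters.

For two sources the decomposition
`T_joint = U_j + U_k + R + S`, `T_j = U_j + R`, `T_k = U_k + R`
is closed in two ways:

* **MMI:** `R = min(T_j, T_k)`. Algebraically closed; when all three
  transfer entropies come from one pooled table, monotonicity of conditional
  mutual information guarantees every component is nonnegative. This is the
  default route and is fully vectorized over triplets.
* **Bertschinger-style:** `S = T(p) − min_q T(q)` over all 16-cell
  distributions `q` preserving the trivariate marginals `(s̃_i, s_i, s_j)`
  and `(s̃_i, s_i, s_k)` of `p`. The original construction fixes the static
  pairwise (target, source) marginals; in the lagged setting the target
  variable is effectively the pair `(s̃_i, s_i)`, so the lifted constraint
  fixes those trivariate marginals — a declared interpretation. For binary
  spins the feasible set is a box in 4 coordinates (one free cell per
  `(s̃_i, s_i)` block) and the objective is convex; a bounded L-BFGS-B
  search from the independent-within-block start, the measured table, and 8
  deterministic random starts converges to ~1e-9. On spin-derived triplet
  tables the two closures agree to well under 0.01 bits (asserted over 100+
  tables spanning the transition region), so MMI is used wherever triplet
  counts are large.

## Triplets and node profiles

A triplet is a target with an unordered source pair. Dense mode enumerates
all `N·C(N−1, 2)` triplets (seeded uniform subsample above a cap — the
per-node mean is unbiased under uniform subsampling); sparse mode keeps
triplets whose two source→target links both survive a density threshold
(default: the smallest `J_th` retaining at most 20% of node pairs, ties
excluded so the target density is never exceeded). A node's *incoming
synergy* is the arithmetic mean of `S` over triplets targeting it; nodes
with no qualifying triplet report NaN, never 0, so cohort averages are not
silently diluted. A built-in robustness check recomputes the profile at
densities 0.15/0.20/0.25 and reports the rank stability.

Typical outgoing (incoming) transfer entropy of a node is the mean pairwise
TE over all targets (drivers), computed from vectorized 8-cell tables.

Centrality uses edge lengths `1/weight` — the streamline-count convention in
which heavy edges are short — with weighted betweenness normalized to [0, 1]
and Wasserman-Faust closeness (per-component, with a warning, on
disconnected graphs); a binarized variant is available since the weighted
choice is a convention, not a measurement.

## Synthetic data

The generator emulates the *statistical structure* of a life-span
connectome study, not its biophysics:

* **Lattices** for validation: 4-neighbor periodic, uniform coupling (the
  2×2 case merges doubly wrapped edges into weight-2J edges).
* **Heterogeneous connectomes:** edge weight = `f_i f_j` × lognormal noise
  (σ = 0.8), where the node fitness `f` follows a Pareto law with tail
  exponent 2.0. Fitness values are deterministic Pareto *quantiles* assigned
  in seeded random order rather than i.i.d. draws: the heavy-tailed strength
  profile (spanning roughly an order of magnitude, as in streamline-count
  data) is a stable feature of the system being emulated, and quantile
  spacing reproduces it in every realization, whereas i.i.d. draws at a few
  dozen nodes oscillate between near-homogeneous and single-superhub
  networks. The top 10% of fitness nodes have their mutual edges boosted
  ×4, planting a rich club interlinked by the largest weights.
* **Aging cohorts:** ages uniform over 4–85 years. Each planted effect
  steers one node's *strength* along a linear or saturating (ramp-then-
  plateau) curve of age; the subject matrix is obtained by symmetric
  Sinkhorn rescaling of the base connectome to the target strengths, so
  non-effect nodes keep their baseline strength exactly. This localizes the
  planted signal, emulating the large-network limit in which one region's
  change is negligible for each partner (at a few dozen nodes, naive edge
  scaling measurably shifts every partner's strength). Multiplicative
  lognormal edge noise (default dispersion 0.1) and deterministic
  weakest-edge sparsification follow.

The recovery experiment (`planted_recovery_spec`) plants ±5%-per-decade
linear effects — the magnitude of structural connectivity change reported
across the adult life span — on the five weakest nodes (three increasing,
two decreasing) with noise dispersion 0.2. Weak nodes sit on the rising
branch of the synergy-versus-strength curve, so their incoming synergy
responds monotonically with the planted sign, and as sources they carry
minimal coupling mass. Its cohort analysis uses dense triplet selection:
the synthetic subject matrices are dense, and sparse selection at 30 nodes
leaves so few triplets per node that a single planted source dominates its
neighbors' averages.

What passing these tests does *not* show: the generator has no spatial
embedding or distance-dependent wiring, so empirical relations that depend
on brain geometry (for example which centrality best predicts synergy) are
not expected to reproduce; recovery at 30 nodes says nothing about power at
a 188-node, 196-subject scale.

## Robust age association

Per node, the synergy column (each subject evaluated at its own
interpolated critical β) is tested against age with a *skipped* Spearman
correlation: bivariate outliers are flagged by the projection rule —
MAD-median distances along every direction from the Weiszfeld spatial
median through a data point, cutoff `sqrt(χ²₀.₉₇₅(2)) ≈ 2.72` — and the
rank correlation is computed on the survivors. The two-sided p value comes
from a seeded Monte-Carlo permutation null of the *entire* skipped
statistic (outlier detection re-run in every permutation, default 1000
permutations, fully vectorized). Detection must sit inside the resampling:
permuting or bootstrapping only the surviving points ignores the
data-adaptive selection and measured a type-I rate of ~0.12 at n = 50,
versus ~0.03–0.05 for the full-statistic permutation (the suite asserts the
[0.02, 0.09] band). Note the permutation p floor is `1/(B+1)`; with m
simultaneous tests, Hochberg can only reject if `(m − k + 1)/(B+1) ≤ α` for
the k tied smallest p values, so B must scale with m/α (the cohort default
B = 1000 supports m = 30 at α = 0.05 comfortably).

Family-wise error over nodes is controlled with Hochberg's step-up
procedure (via statsmodels); degenerate zero-variance columns report
ρ = 0, p = 1 with a flag rather than aborting a cohort run. A follow-up
applies the same machinery to raw node strength, separating synergy trends
explained by connectivity change from those that are not.

## Reproducibility

All randomness descends from one master seed through a pure derivation
(CRC-hashed stage/run/subject tokens feeding a seed sequence), so partial
reruns and parallel execution reproduce exactly; artifact bundles are
stamped with a configuration hash. The Glauber kernel and triplet counting
are numba-compiled; everything else is numpy/scipy vectorized.

## Known limitations

* Plugin TE is biased upward at small sample counts; comparisons across
  conditions with equal series length are unaffected, absolute values are
  not. No Miller-Madow correction is applied by default.
* The Bertschinger optimizer solves a 4-dimensional box-constrained convex
  program per triplet (~0.1 s); use MMI for large triplet sets.
* Global transfer entropy (all N−1 drivers) is out of scope: the 2^(N+1)
  cell plugin table is infeasible beyond a handful of spins.
* The susceptibility peak of a strongly heterogeneous network is broad
  (criticality is stretched over a β range), so the "critical β" is a
  convention; per-node synergy peaks spread around it, which is precisely
  the precursor phenomenon the pipeline measures.
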