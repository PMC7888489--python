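"""Synthetic connectomes and aging cohorts.

Provides the three kinds of input the pipeline needs without any download:

* periodic 2D lattices, the classical validation surface for Ising dynamics;
* heterogeneous dense connectomes with heavy-tailed node strengths and a
  planted rich-club core, emulating a group-average structural connectome;
* cohorts of per-subject connectomes with node-specific age effects planted
  on top of a shared base network, emulating a life-span study.

The generative model is deliberately simple: base weights are lognormal,
modulated by per-node "fitness" factors following a Pareto law (which yields
heavy-tailed strengths and, when the top-fitness nodes are boosted towards
each other, a rich club).  Age effects steer the *strength* of chosen nodes
along a linear or saturating curve of the subject's age, with the rest of
the network rescaled so non-effect nodes keep their baseline strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .connectome import CohortManifest, ConnectivityMatrix

__all__ = [
    "AgingEffectSpec",
    "CohortSpec",
    "base_connectome",
    "generate_lattice2d",
    "generate_heterogeneous_connectome",
    "generate_aging_cohort",
    "materialize_cohort",
    "planted_recovery_spec",
]


def generate_lattice2d(L: int, J: float = 1.0) -> ConnectivityMatrix:
    """Periodic square lattice of side ``L`` with uniform coupling ``J``.

    Every node couples to its 4 nearest neighbors with weight ``J`` and has
    strength ``4 J``.  For ``L == 2`` the periodic wrap makes each neighbor
    pair doubly connected, so the merged edge weight is ``2 J`` (strength is
    still ``4 J``).
    """
    if L < 2:
        raise ValueError("lattice side L must be >= 2")
    n = L * L
    w = np.zeros((n, n))
    for x in range(L):
        for y in range(L):
            i = x * L + y
            for dx, dy in ((1, 0), (0, 1)):
                j = ((x + dx) % L) * L + (y + dy) % L
                w[i, j] += J
                w[j, i] += J
    return ConnectivityMatrix(weights=w)


def generate_heterogeneous_connectome(
    n_nodes: int,
    strength_tail_exponent: float = 2.0,
    rich_club_fraction: float = 0.1,
    seed: int = 0,
    weight_sigma: float = 0.8,
    rich_club_boost: float = 4.0,
) -> ConnectivityMatrix:
    """Dense symmetric connectome with heavy-tailed strengths and a rich club.

    Node fitness factors ``f_i`` follow a Pareto law with the requested tail
    exponent; the weight of edge (i, j) is ``f_i f_j`` times lognormal noise,
    which makes node strengths approximately proportional to fitness (hence
    heavy-tailed, spanning roughly an order of magnitude as in empirical
    streamline-count connectomes).  Edges among the ``rich_club_fraction``
    highest-fitness nodes are additionally multiplied by ``rich_club_boost``,
    planting a core of hubs interlinked by the largest weights.

    Fitness values are deterministic Pareto quantiles (inverse CDF at evenly
    spaced probabilities) assigned to nodes in seeded random order, rather
    than i.i.d. draws: the heavy-tailed strength *profile* is a stable
    feature of real connectomes, and quantile spacing reproduces it in every
    realization instead of only on average (i.i.d. Pareto draws at modest
    ``n_nodes`` oscillate between near-homogeneous and single-superhub
    networks, neither of which resembles the system being emulated).
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    if not 0.0 <= rich_club_fraction <= 1.0:
        raise ValueError("rich_club_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alpha = strength_tail_exponent
    q = (np.arange(n_nodes) + 0.5) / n_nodes
    fitness = rng.permutation((1.0 - q) ** (-1.0 / alpha))
    w = np.outer(fitness, fitness) * rng.lognormal(
        mean=0.0, sigma=weight_sigma, size=(n_nodes, n_nodes)
    )
    w = np.triu(w, k=1)
    n_core = int(round(rich_club_fraction * n_nodes))
    if n_core >= 2:
        core = np.argsort(fitness)[::-1][:n_core]
        boost = np.ones_like(w)
        boost[np.ix_(core, core)] = rich_club_boost
        w *= boost
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w)


@dataclass(frozen=True)
class AgingEffectSpec:
    """Age effect planted on one node.

    The node's *strength* is multiplied by a curve of the subject's age
    (floored at 5% of baseline).  ``effect_size`` is the relative change per
    decade; a ``saturating`` curve ramps linearly until ``saturation_age``
    and is flat afterwards (an early-life increase followed by a plateau,
    the second pattern seen in life-span connectome studies).
    """

    node: int
    direction: Literal["increasing", "decreasing"] = "decreasing"
    shape: Literal["linear", "saturating"] = "linear"
    effect_size: float = 0.10
    saturation_age: float = 30.0

    def factor(self, age: float, age_min: float) -> float:
        """Multiplicative weight factor at a given age (1.0 at ``age_min``)."""
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        eff_age = age
        if self.shape == "saturating":
            eff_age = min(age, self.saturation_age)
        decades = (eff_age - age_min) / 10.0
        slope = self.effect_size if self.direction == "increasing" else -self.effect_size
        return float(max(1.0 + slope * decades, 0.05))


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic aging cohort.

    Defaults mirror a life-span structural-connectivity study: ages span
    4–85 years, individual matrices are noisy, sparsified versions of a dense
    base connectome, and a handful of nodes carry planted age effects.
    """

    n_subjects: int = 196
    n_nodes: int = 188
    age_range: tuple[float, float] = (4.0, 85.0)
    effects: tuple[AgingEffectSpec, ...] = ()
    noise_sigma: float = 0.1
    sparsity: float = 0.5
    seed: int = 0
    # cohort bases use a slightly shallower tail than the standalone
    # generator default: individual networks are less hub-dominated than
    # the group average they are drawn around
    strength_tail_exponent: float = 3.0
    rich_club_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must be in [0, 1)")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        for e in self.effects:
            if not 0 <= e.node < self.n_nodes:
                raise ValueError(f"effect node {e.node} out of range")
            if e.shape == "saturating" and not lo <= e.saturation_age <= hi:
                raise ValueError("saturation_age outside the cohort age range")


def base_connectome(spec: CohortSpec) -> ConnectivityMatrix:
    """The shared base connectome a cohort spec would build on.

    Depends only on the spec's seed and network parameters, never on the
    planted effects — so callers can inspect the base (e.g. pick effect nodes
    by strength rank) and then regenerate the cohort with effects added.
    """
    rng = np.random.default_rng(spec.seed)
    return generate_heterogeneous_connectome(
        spec.n_nodes,
        strength_tail_exponent=spec.strength_tail_exponent,
        rich_club_fraction=spec.rich_club_fraction,
        seed=int(rng.integers(2**31 - 1)),
    )


def planted_recovery_spec(
    seed: int,
    n_subjects: int = 60,
    n_nodes: int = 30,
    n_increasing: int = 3,
    n_decreasing: int = 2,
    effect_size: float = 0.05,
    noise_sigma: float = 0.2,
) -> tuple[CohortSpec, dict[int, int]]:
    """Cohort spec for a planted-signal recovery experiment.

    Plants linear age effects (default ±5% strength change per decade, the
    magnitude of structural connectivity change reported across the adult
    life span) on the lowest-strength nodes of the base connectome,
    alternating increasing and decreasing.  Weak nodes sit on the rising
    branch of the synergy-versus-strength curve, so their incoming synergy
    responds monotonically to the planted connectivity change, and as
    sources they carry the least coupling mass, which keeps the planted
    signal localized.  Returns the spec and a {node: expected sign} map.
    """
    spec0 = CohortSpec(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        noise_sigma=noise_sigma,
        sparsity=0.0,
        seed=seed,
    )
    ranks = np.argsort(base_connectome(spec0).strength())
    effects: list[AgingEffectSpec] = []
    planted: dict[int, int] = {}
    inc_left, dec_left = n_increasing, n_decreasing
    for a in range(n_increasing + n_decreasing):
        node = int(ranks[1 + a])
        if dec_left == 0 or (a % 2 == 0 and inc_left > 0):
            direction, inc_left = "increasing", inc_left - 1
        else:
            direction, dec_left = "decreasing", dec_left - 1
        effects.append(
            AgingEffectSpec(node=node, direction=direction, shape="linear",
                            effect_size=effect_size)
        )
        planted[node] = 1 if direction == "increasing" else -1
    import dataclasses

    return dataclasses.replace(spec0, effects=tuple(effects)), planted


def _scale_to_strengths(
    w: np.ndarray, target: np.ndarray, n_iter: int = 60
) -> np.ndarray:
    """Symmetric Sinkhorn scaling of a weight matrix to target node strengths.

    Finds a diagonal rescaling ``D W D`` whose row sums match ``target``,
    so a planted change in one node's strength leaves every other node's
    strength at baseline instead of bleeding into all of its partners.
    """
    d = np.ones_like(target)
    for _ in range(n_iter):
        s = (w * np.outer(d, d)).sum(axis=1)
        d *= np.sqrt(target / np.maximum(s, 1e-300))
    return w * np.outer(d, d)


def generate_aging_cohort(
    spec: CohortSpec,
) -> tuple[CohortManifest, list[ConnectivityMatrix]]:
    """Cohort of per-subject connectomes with planted age effects.

    Subject ages are uniform over the age range.  Each subject matrix is the
    shared base connectome with (1) each effect node's *strength* steered
    along its age curve — the matrix is Sinkhorn-rescaled so that non-effect
    nodes keep their baseline strength, emulating the large-network limit in
    which a single region's change is locally negligible for its partners —
    (2) i.i.d. multiplicative lognormal noise of dispersion ``noise_sigma``
    on every edge, and (3) the weakest edges removed until the requested
    fraction of node pairs is zero — mimicking the dropout of weak
    connections in individual tractography.

    The manifest's ``paths`` are placeholder names; use
    :func:`connsyn.connectome.save_connectome` to materialize files.
    """
    rng = np.random.default_rng(spec.seed)
    rng.integers(2**31 - 1)  # keep the stream aligned with base_connectome
    base = base_connectome(spec)
    lo, hi = spec.age_range
    ages = np.sort(rng.uniform(lo, hi, size=spec.n_subjects))
    n = spec.n_nodes
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    n_drop = int(np.floor(spec.sparsity * n_pairs))
    base_strength = base.weights.sum(axis=1)
    matrices: list[ConnectivityMatrix] = []
    for age in ages:
        target = base_strength.copy()
        for eff in spec.effects:
            target[eff.node] *= eff.factor(float(age), lo)
        w = _scale_to_strengths(base.weights, target)
        if spec.noise_sigma > 0:
            noise = rng.lognormal(0.0, spec.noise_sigma, size=(n, n))
            noise = np.triu(noise, k=1)
            noise = noise + noise.T
            w *= noise
        if n_drop > 0:
            vals = w[iu]
            cut = np.partition(vals, n_drop - 1)[n_drop - 1]
            kill = vals <= cut
            # drop exactly n_drop: break ties by index order
            extra = kill.sum() - n_drop
            if extra > 0:
                tied = np.flatnonzero(kill & (vals == cut))
                kill[tied[:extra]] = False
            vals = vals.copy()
            vals[kill] = 0.0
            w = np.zeros_like(w)
            w[iu] = vals
            w = w + w.T
        matrices.append(ConnectivityMatrix(weights=w, labels=base.labels))
    manifest = CohortManifest(
        subject_ids=tuple(f"sub-{i:04d}" for i in range(spec.n_subjects)),
        ages=ages,
        paths=tuple(f"sub-{i:04d}.csv" for i in range(spec.n_subjects)),
    )
    return manifest, matrices


def materialize_cohort(
    manifest: CohortManifest,
    matrices: list[ConnectivityMatrix],
    out_dir,
    spec: CohortSpec | None = None,
) -> CohortManifest:
    """Write a generated cohort to disk in the standard text dialect.

    Saves one matrix file per subject, a manifest CSV pointing at them, and
    (if given) the generating spec as a human-readable key-value config.
    Returns a manifest whose paths are the written files.
    """
    from pathlib import Path

    from .connectome import save_connectome, save_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, m in zip(manifest.paths, matrices):
        p = out / name
        save_connectome(m, p)
        paths.append(str(p))
    disk = CohortManifest(
        subject_ids=manifest.subject_ids, ages=manifest.ages, paths=tuple(paths)
    )
    save_manifest(disk, out / "manifest.csv")
    if spec is not None:
        lines = [
            f"n_subjects = {spec.n_subjects}",
            f"n_nodes = {spec.n_nodes}",
            f"age_range = {spec.age_range[0]} {spec.age_range[1]}",
            f"noise_sigma = {spec.noise_sigma}",
            f"sparsity = {spec.sparsity}",
            f"seed = {spec.seed}",
            f"strength_tail_exponent = {spec.strength_tail_exponent}",
            f"rich_club_fraction = {spec.rich_club_fraction}",
        ]
        for e in spec.effects:
            lines.append(
                f"effect = node:{e.node} {e.direction} {e.shape} "
                f"size:{e.effect_size} saturation:{e.saturation_age}"
            )
        (out / "cohort_spec.cfg").write_text("\n".join(lines) + "\n")
    return disk
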