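"""Transfer entropy and partial information decomposition for binary spins.

Transfer entropy from sources ``{s_j, s_k}`` to target ``s_i`` is the
conditional mutual information ``I(s~_i ; s_j, s_k | s_i)`` between the
target's next state ``s~_i`` and the sources' present states, given the
target's present state.  For two sources the joint transfer entropy splits
into unique, redundant and synergistic components:

    T_{jk->i} = U_j + U_k + R + S,    T_j = U_j + R,    T_k = U_k + R.

Two closures of this underdetermined system are provided: the
minimum-mutual-information (MMI) definition ``R = min(T_j, T_k)``, and the
Bertschinger-style definition of synergy as the excess of the measured joint
transfer entropy over the smallest joint transfer entropy compatible with
the target-source marginals (a 4-dimensional convex minimization for binary
spins).

All distributions are plugin estimates: configuration frequencies read
directly off the spin time series, with counts pooled across runs.
Information is measured in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .ising import SpinTimeSeries

__all__ = [
    "LaggedJointDistribution",
    "PIDResult",
    "estimate_lagged_joint",
    "conditional_mutual_information",
    "transfer_entropy",
    "pid_mmi",
    "pid_bertschinger",
    "pid_from_distribution",
]

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class LaggedJointDistribution:
    """Plugin joint distribution over (future target, present target, sources).

    ``table`` has shape (2, 2, 2) for one source or (2, 2, 2, 2) for two,
    with axis order (s~_i, s_i, s_j[, s_k]) and index 0 for spin −1, 1 for
    spin +1.  Normalized to sum 1.
    """

    table: np.ndarray
    sample_count: int

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape not in ((2, 2, 2), (2, 2, 2, 2)):
            raise ValueError(f"table must be 8 or 16 cells, got shape {t.shape}")
        if np.any(t < -1e-15):
            raise ValueError("negative probabilities in table")
        if abs(t.sum() - 1.0) > 1e-12:
            raise ValueError("table does not sum to 1")
        t = np.clip(t, 0.0, None)
        t.flags.writeable = False
        object.__setattr__(self, "table", t)

    @property
    def n_sources(self) -> int:
        return self.table.ndim - 2

    def to_json(self) -> str:
        """Serialize as an ordered cell -> probability mapping.

        Cell keys are spin patterns like ``"+-++"`` in the table's axis
        order (future target, present target, sources), '+' for +1.
        """
        import itertools as it
        import json

        cells = {}
        for idx in it.product((0, 1), repeat=self.table.ndim):
            key = "".join("+" if b else "-" for b in idx)
            cells[key] = float(self.table[idx])
        return json.dumps({"cells": cells, "sample_count": self.sample_count})

    @classmethod
    def from_json(cls, text: str) -> "LaggedJointDistribution":
        import json

        payload = json.loads(text)
        cells = payload["cells"]
        ndim = len(next(iter(cells)))
        table = np.zeros((2,) * ndim)
        for key, p in cells.items():
            idx = tuple(1 if ch == "+" else 0 for ch in key)
            table[idx] = p
        return cls(table=table, sample_count=int(payload["sample_count"]))

    def marginal_over_source(self, drop: int) -> "LaggedJointDistribution":
        """8-cell marginal dropping one of two sources (0 -> s_j, 1 -> s_k)."""
        if self.n_sources != 2:
            raise ValueError("marginal_over_source needs a two-source table")
        axis = 2 if drop == 0 else 3
        out = self.table.sum(axis=axis)
        return LaggedJointDistribution(table=out, sample_count=self.sample_count)


@dataclass(frozen=True)
class PIDResult:
    """Transfer entropies and their PID components for one triplet (bits)."""

    T_joint: float
    T_j: float
    T_k: float
    U_j: float
    U_k: float
    R: float
    S: float
    method: str

    def __post_init__(self) -> None:
        tol = 1e-9
        closure = abs(self.T_joint - (self.U_j + self.U_k + self.R + self.S))
        if closure > tol or abs(self.T_j - (self.U_j + self.R)) > tol or abs(
            self.T_k - (self.U_k + self.R)
        ) > tol:
            raise ValueError("PID components do not close the decomposition")


def _bits01(samples: np.ndarray) -> np.ndarray:
    return (samples > 0).astype(np.int64)


def estimate_lagged_joint(
    series: SpinTimeSeries | Sequence[SpinTimeSeries],
    target: int,
    sources: Sequence[int],
    lag: int = 1,
) -> LaggedJointDistribution:
    """Plugin lagged joint distribution, pooling counts over runs.

    Counts configurations ``(s_i(t+lag), s_i(t), s_src(t)...)`` over all valid
    ``t`` in every provided run, then normalizes once — so pooled runs
    contribute in proportion to their length.
    """
    runs = [series] if isinstance(series, SpinTimeSeries) else list(series)
    sources = list(sources)
    if target in sources:
        raise ValueError("target must not be one of the sources")
    if len(sources) not in (1, 2):
        raise ValueError("need 1 or 2 sources")
    n_cells = 2 ** (2 + len(sources))
    counts = np.zeros(n_cells, dtype=np.int64)
    total = 0
    for run in runs:
        if run.n_sweeps <= lag:
            raise ValueError("series shorter than the lag")
        b = _bits01(run.samples)
        code = b[lag:, target]
        code = code * 2 + b[:-lag, target]
        for s in sources:
            code = code * 2 + b[:-lag, s]
        counts += np.bincount(code, minlength=n_cells)
        total += run.n_sweeps - lag
    table = (counts / total).reshape((2,) * (2 + len(sources)))
    return LaggedJointDistribution(table=table, sample_count=total)


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def conditional_mutual_information(
    p: LaggedJointDistribution | np.ndarray,
    x_axes: Sequence[int],
    y_axes: Sequence[int],
    z_axes: Sequence[int],
) -> float:
    """Conditional mutual information I(X; Y | Z) in bits.

    ``x_axes``, ``y_axes``, ``z_axes`` partition (a subset of) the table's
    axes.  Zero-probability cells contribute zero (0 log 0 = 0), as do terms
    with zero conditioning mass.
    """
    table = p.table if isinstance(p, LaggedJointDistribution) else np.asarray(p)
    axes = set(x_axes) | set(y_axes) | set(z_axes)
    if len(axes) != len(x_axes) + len(y_axes) + len(z_axes):
        raise ValueError("axis groups must be disjoint")
    drop = tuple(a for a in range(table.ndim) if a not in axes)
    if drop:
        table = table.sum(axis=drop, keepdims=False)
        remap = {a: i for i, a in enumerate(sorted(axes))}
        x_axes = [remap[a] for a in x_axes]
        y_axes = [remap[a] for a in y_axes]
        z_axes = [remap[a] for a in z_axes]
    def marg(keep):
        s = tuple(a for a in range(table.ndim) if a not in keep)
        return table.sum(axis=s) if s else table
    # I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z)
    def ent(t):
        return -_xlogx(np.asarray(t, dtype=float).ravel()).sum() / _LOG2
    h_xz = ent(marg(set(x_axes) | set(z_axes)))
    h_yz = ent(marg(set(y_axes) | set(z_axes)))
    h_xyz = ent(marg(set(x_axes) | set(y_axes) | set(z_axes)))
    h_z = ent(marg(set(z_axes))) if z_axes else 0.0
    return max(h_xz + h_yz - h_xyz - h_z, 0.0)


def te_from_table(p: LaggedJointDistribution | np.ndarray) -> float:
    """Transfer entropy of a lagged joint table: I(s~_i ; sources | s_i)."""
    table = p.table if isinstance(p, LaggedJointDistribution) else np.asarray(p)
    src_axes = list(range(2, table.ndim))
    return conditional_mutual_information(table, [0], src_axes, [1])


def transfer_entropy(
    series: SpinTimeSeries | Sequence[SpinTimeSeries],
    target: int,
    sources: Sequence[int],
    lag: int = 1,
) -> float:
    """Plugin transfer entropy (bits) from 1 or 2 sources to a target."""
    return te_from_table(estimate_lagged_joint(series, target, sources, lag))


def pid_mmi(T_joint: float, T_j: float, T_k: float, tol: float = 1e-7) -> PIDResult:
    """Minimum-mutual-information PID: redundancy is min(T_j, T_k).

    Requires ``T_joint >= max(T_j, T_k)`` (up to ``tol``), which holds
    exactly when all three transfer entropies come from one pooled
    distribution (monotonicity of conditional mutual information).
    """
    for v in (T_joint, T_j, T_k):
        if not np.isfinite(v):
            raise ValueError("transfer entropies must be finite")
    if T_joint < max(T_j, T_k) - tol:
        raise ValueError(
            "inconsistent inputs: T_joint < max(T_j, T_k) beyond tolerance"
        )
    T_joint = max(T_joint, max(T_j, T_k))
    r = min(T_j, T_k)
    u_j = T_j - r
    u_k = T_k - r
    s = T_joint - T_j - T_k + r
    return PIDResult(
        T_joint=T_joint, T_j=T_j, T_k=T_k, U_j=u_j, U_k=u_k, R=r, S=s,
        method="MMI",
    )


def pid_from_distribution(
    p: LaggedJointDistribution, method: str = "MMI"
) -> PIDResult:
    """PID of a two-source lagged joint, all terms from the same table."""
    if p.n_sources != 2:
        raise ValueError("need a two-source (16-cell) distribution")
    if method.upper() == "MMI":
        t_joint = te_from_table(p)
        t_j = te_from_table(p.table.sum(axis=3))
        t_k = te_from_table(p.table.sum(axis=2))
        return pid_mmi(t_joint, t_j, t_k)
    if method.lower() == "bertschinger":
        return pid_bertschinger(p)
    raise ValueError(f"unknown PID method: {method!r}")


def _assemble_q(t: np.ndarray, a1: np.ndarray, b1: np.ndarray, nb: np.ndarray) -> np.ndarray:
    """Build the 16-cell q from the 4 free block parameters.

    Per (s~, s) block the 2x2 source table has fixed margins: row sums
    (a0, a1) over s_j and column sums (b0, b1) over s_k; the free parameter
    is ``t = q(s_j=1, s_k=1 | block)`` in absolute probability.
    """
    q = np.empty((4, 2, 2))
    q[:, 1, 1] = t
    q[:, 1, 0] = a1 - t
    q[:, 0, 1] = b1 - t
    q[:, 0, 0] = nb - a1 - b1 + t
    return q.reshape(2, 2, 2, 2)


def pid_bertschinger(
    p: LaggedJointDistribution,
    tol: float = 1e-9,
    n_multistart: int = 8,
) -> PIDResult:
    """Bertschinger-style PID by constrained minimization.

    The synergy is ``S = T(p) - min_q T(q)`` over all 16-cell distributions
    ``q`` that preserve the trivariate marginals ``(s~_i, s_i, s_j)`` and
    ``(s~_i, s_i, s_k)`` of ``p`` (the lagged lift of the original
    static-marginal constraints).  With binary variables the feasible set is
    a box in 4 free coordinates (one per (s~_i, s_i) block) and the objective
    is convex; a bounded quasi-Newton search from deterministic multi-starts
    is used.  The remaining components follow from the decomposition
    identities, with the single-source transfer entropies computed from the
    (fixed) marginals.
    """
    if p.n_sources != 2:
        raise ValueError("need a two-source (16-cell) distribution")
    table = p.table
    t_joint = te_from_table(table)
    t_j = te_from_table(table.sum(axis=3))
    t_k = te_from_table(table.sum(axis=2))
    blocks = table.reshape(4, 2, 2)
    nb = blocks.sum(axis=(1, 2))
    a1 = blocks[:, 1, :].sum(axis=1)  # mass with s_j = +1 per block
    b1 = blocks[:, :, 1].sum(axis=1)  # mass with s_k = +1 per block
    lo = np.maximum(0.0, a1 + b1 - nb)
    hi = np.minimum(a1, b1)

    def objective(t: np.ndarray) -> float:
        q = _assemble_q(np.clip(t, lo, hi), a1, b1, nb)
        return te_from_table(q)

    starts = [np.where(nb > 0, a1 * b1 / np.where(nb > 0, nb, 1.0), 0.0)]
    starts.append(table[:, :, 1, 1].reshape(4))  # the measured p itself
    rng = np.random.default_rng(12345)
    for _ in range(n_multistart):
        starts.append(lo + (hi - lo) * rng.random(4))
    best_val, best_ok = np.inf, False
    for x0 in starts:
        res = minimize(
            objective,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": tol, "gtol": 1e-12, "maxiter": 500},
        )
        if res.fun < best_val:
            best_val, best_ok = float(res.fun), bool(res.success)
    if not np.isfinite(best_val):
        raise RuntimeError("Bertschinger minimization failed to produce a bound")
    s = max(t_joint - best_val, 0.0)
    r = max(t_j + t_k + s - t_joint, 0.0)
    s = t_joint - t_j - t_k + r  # re-close exactly after clamping
    return PIDResult(
        T_joint=t_joint, T_j=t_j, T_k=t_k,
        U_j=t_j - r, U_k=t_k - r, R=r, S=s,
        method="Bertschinger",
    )
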