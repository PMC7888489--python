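"""Robust association between per-node synergy and age across a cohort.

The workhorse is the *skipped* Spearman correlation: bivariate outliers are
removed by a projection rule about the spatial median (MAD-median distances
along the directions through each data point, cutoff sqrt(chi2_{0.975}(2))),
the Spearman coefficient is computed on the survivors, and a percentile
bootstrap of the skipped estimator supplies the p value.  Family-wise error
over nodes is controlled with Hochberg's step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import ConnectivityMatrix

__all__ = [
    "CohortSynergyTable",
    "detect_bivariate_outliers",
    "skipped_spearman",
    "hochberg_adjust",
    "run_age_analysis",
    "strength_age_followup",
]

_CHI2_CUTOFF = float(np.sqrt(stats.chi2.ppf(0.975, df=2)))


@dataclass(frozen=True)
class CohortSynergyTable:
    """Subjects x nodes incoming-synergy matrix with ages and per-subject beta*.

    Each row is one subject's per-node synergy profile evaluated at that
    subject's own critical beta.
    """

    synergy: np.ndarray  # (n_subjects, n_nodes)
    ages: np.ndarray
    critical_betas: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        syn = np.asarray(self.synergy, dtype=float)
        ages = np.asarray(self.ages, dtype=float)
        if syn.ndim != 2 or syn.shape[0] != ages.size:
            raise ValueError("synergy must be (n_subjects, n_nodes)")
        if not np.all(np.isfinite(ages)):
            raise ValueError("ages must be finite")
        object.__setattr__(self, "synergy", syn)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(
            self, "critical_betas", np.asarray(self.critical_betas, dtype=float)
        )

    @property
    def n_subjects(self) -> int:
        return self.synergy.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.synergy.shape[1]


def _spatial_median(z: np.ndarray, tol: float = 1e-9, max_iter: int = 200) -> np.ndarray:
    """Weiszfeld iteration for the L1 (geometric) median of 2-D points."""
    center = np.median(z, axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(z - center, axis=1)
        if np.any(d < 1e-12):
            # a data point is the median candidate; nudge off the singularity
            d = np.maximum(d, 1e-12)
        w = 1.0 / d
        new = (z * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - center) < tol:
            return new
        center = new
    return center


def _projection_outliers(z: np.ndarray) -> np.ndarray:
    """Vectorized projection rule: flag points extreme on any direction
    from the spatial median through a data point (MAD-median distances)."""
    center = _spatial_median(z)
    diffs = z - center
    norms = np.linalg.norm(diffs, axis=1)
    ok = norms > 1e-12
    dirs = diffs[ok] / norms[ok, None]
    proj = diffs @ dirs.T  # (n_points, n_directions)
    med = np.median(proj, axis=0)
    mad = np.median(np.abs(proj - med), axis=0) / 0.6745
    good = mad > 1e-12
    if not good.any():
        return np.zeros(z.shape[0], dtype=bool)
    dist = np.abs(proj[:, good] - med[good]) / mad[good]
    return (dist > _CHI2_CUTOFF).any(axis=1)


def _skipped_rho_batch(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Skipped Spearman rho of x against every row of Y, detection included.

    Fully vectorized over the batch: Weiszfeld spatial medians, projection
    outlier flags and NaN-aware rank correlations are computed for all rows
    at once.  Rows with fewer than 5 survivors yield NaN.
    """
    Y = np.asarray(Y, dtype=float)
    B, n = Y.shape
    z = np.empty((B, n, 2))
    z[:, :, 0] = x[None, :]
    z[:, :, 1] = Y
    centers = np.median(z, axis=1)
    scale = np.maximum(np.abs(z).max(), 1.0)
    # 40 fixed iterations give the spatial median to far better precision
    # than the 2.72-MAD flag boundary requires, and keep the batch cheap
    for _ in range(40):
        d = np.linalg.norm(z - centers[:, None, :], axis=2)
        w = 1.0 / np.maximum(d, 1e-12)
        new = (z * w[:, :, None]).sum(axis=1) / w.sum(axis=1)[:, None]
        done = np.abs(new - centers).max() < 1e-6 * scale
        centers = new
        if done:
            break
    diffs = z - centers[:, None, :]
    norms = np.linalg.norm(diffs, axis=2)
    dirs = diffs / np.maximum(norms, 1e-12)[:, :, None]
    proj = np.einsum("bnd,bmd->bnm", diffs, dirs)  # point n on direction m
    med = np.median(proj, axis=1)
    mad = np.median(np.abs(proj - med[:, None, :]), axis=1) / 0.6745
    usable = (mad > 1e-12) & (norms > 1e-12)
    dist = np.abs(proj - med[:, None, :]) / np.maximum(mad, 1e-12)[:, None, :]
    flagged = (dist > _CHI2_CUTOFF) & usable[:, None, :]
    outlier = flagged.any(axis=2)
    xs = np.where(outlier, np.nan, x[None, :])
    ys = np.where(outlier, np.nan, Y)
    rx = stats.rankdata(xs, axis=1, nan_policy="omit")
    ry = stats.rankdata(ys, axis=1, nan_policy="omit")
    rx = rx - np.nanmean(rx, axis=1, keepdims=True)
    ry = ry - np.nanmean(ry, axis=1, keepdims=True)
    num = np.nansum(rx * ry, axis=1)
    den = np.sqrt(np.nansum(rx**2, axis=1) * np.nansum(ry**2, axis=1))
    out = np.full(B, np.nan)
    enough = (~outlier).sum(axis=1) >= 5
    ok = enough & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def detect_bivariate_outliers(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Projection-rule outlier mask (True marks an outlier).

    Points are projected onto every direction from the spatial median
    through a data point; a point is flagged if, on any projection, its
    MAD-median distance exceeds sqrt(chi2_{0.975}(2)).  Deterministic; warns
    when more than 25% of points are flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points for outlier detection")
    z = np.column_stack([x, y])
    flagged = _projection_outliers(z)
    if flagged.sum() > 0.25 * n:
        import warnings

        warnings.warn(
            f"projection rule flagged {flagged.sum()}/{n} points as outliers",
            RuntimeWarning,
            stacklevel=2,
        )
    return flagged


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def skipped_spearman(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Skipped Spearman correlation with a permutation p value.

    Bivariate outliers are removed by the projection rule and Spearman's rho
    is computed on the survivors.  The two-sided p value comes from a seeded
    Monte-Carlo permutation null of the *entire* skipped statistic —
    ``n_boot`` permutations of y, each with its own outlier detection — so
    the data-adaptive point removal cannot inflate the test (removing points
    once and permuting only the survivors, or bootstrapping them, measures a
    type-I rate well above nominal).  Deterministic given ``seed``.
    Degenerate (zero-variance) inputs return ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0

    keep = ~detect_bivariate_outliers(x, y)
    if keep.sum() < 5:
        raise ValueError("fewer than 5 points survive outlier removal")
    rho = _spearman(x[keep], y[keep])
    if not np.isfinite(rho):
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y.size) for _ in range(n_boot)])
    null = _skipped_rho_batch(x, y[perms])
    finite = np.isfinite(null)
    exceed = int(np.count_nonzero(np.abs(null[finite]) >= abs(rho) - 1e-12))
    p = (1.0 + exceed) / (n_boot + 1.0)
    return rho, float(min(p, 1.0))


def hochberg_adjust(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Hochberg step-up adjusted p values and the rejection mask at alpha."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="simes-hochberg")
    return p_adj, reject


def run_age_analysis(
    table: CohortSynergyTable,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-node skipped Spearman of synergy vs age with Hochberg FWER control.

    Returns one row per node with ``rho``, raw and adjusted p values,
    significance at ``alpha``, the sign of the association, the number of
    subjects used after outlier removal, and a degeneracy flag for
    zero-variance columns (reported as rho 0, p 1 rather than aborting).
    Rows are sorted by adjusted p.
    """
    if table.n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    n_nodes = table.n_nodes
    rhos = np.zeros(n_nodes)
    p_raw = np.ones(n_nodes)
    n_used = np.zeros(n_nodes, dtype=int)
    degenerate = np.zeros(n_nodes, dtype=bool)
    for node in range(n_nodes):
        col = table.synergy[:, node]
        ok = np.isfinite(col)
        if ok.sum() < 10 or np.ptp(col[ok]) == 0:
            degenerate[node] = True
            n_used[node] = int(ok.sum())
            continue
        rho, p = skipped_spearman(
            table.ages[ok], col[ok], n_boot=n_boot, seed=seed + node
        )
        keep = ~detect_bivariate_outliers(table.ages[ok], col[ok])
        rhos[node] = rho
        p_raw[node] = p
        n_used[node] = int(keep.sum())
    p_adj, reject = hochberg_adjust(p_raw, alpha=alpha)
    labels = list(table.labels) or [f"node_{i:03d}" for i in range(n_nodes)]
    df = pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "label": labels,
            "rho": rhos,
            "p_raw": p_raw,
            "p_hochberg": p_adj,
            "significant": reject,
            "sign": np.sign(rhos).astype(int),
            "n_used": n_used,
            "degenerate": degenerate,
        }
    )
    return df.sort_values("p_hochberg", kind="stable").reset_index(drop=True)


def strength_age_followup(
    matrices: list[ConnectivityMatrix],
    ages: np.ndarray,
    nodes: np.ndarray | None = None,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Skipped Spearman of node *strength* vs age for selected nodes.

    The same robust machinery applied to the structural strengths, used to
    ask whether a synergy-age association is explained by raw connectivity
    change of those nodes.
    """
    ages = np.asarray(ages, dtype=float)
    if len(matrices) != ages.size:
        raise ValueError("one matrix per age required")
    strengths = np.array([m.strength() for m in matrices])
    n_nodes = strengths.shape[1]
    nodes = np.arange(n_nodes) if nodes is None else np.asarray(nodes, dtype=int)
    table = CohortSynergyTable(
        synergy=strengths[:, nodes],
        ages=ages,
        critical_betas=np.full(ages.size, np.nan),
        labels=tuple(matrices[0].labels[i] for i in nodes),
    )
    out = run_age_analysis(table, alpha=alpha, n_boot=n_boot, seed=seed)
    out["node"] = nodes[out["node"].to_numpy()]
    return out
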