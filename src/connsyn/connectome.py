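"""Weighted structural connectomes: I/O, validation, and graph topology.

A connectome is a symmetric, nonnegative, zero-diagonal weight matrix over
labeled nodes (weights ~ streamline counts from tractography).  This module
reads and writes the dense text dialect used by connectome databases, averages
cohorts, applies density thresholds, and computes the node topology metrics
(strength, betweenness, closeness) used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "CohortManifest",
    "NodeTopologyProfile",
    "load_connectome",
    "save_connectome",
    "average_connectomes",
    "density_threshold",
    "node_strength",
    "centrality_metrics",
    "rich_club_check",
    "load_manifest",
    "save_manifest",
]

_ASYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative weighted graph over labeled nodes.

    Parameters
    ----------
    weights
        ``(n, n)`` array, symmetric, zero diagonal, all entries >= 0.
    labels
        Node names, length ``n``.  Defaults to ``node_000 ...``.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain NaN or Inf")
        if np.any(w < 0):
            raise ValueError("weights contain negative entries")
        scale = max(np.abs(w).max(), 1.0)
        if np.abs(w - w.T).max() > _ASYMMETRY_RTOL * scale:
            raise ValueError("weight matrix is asymmetric beyond tolerance")
        w = 0.5 * (w + w.T)  # absorb text round-off
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        labels = tuple(self.labels) or tuple(
            f"node_{i:03d}" for i in range(w.shape[0])
        )
        if len(labels) != w.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {w.shape[0]} nodes"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def strength(self) -> np.ndarray:
        """Per-node strength: sum of incident edge weights."""
        return self.weights.sum(axis=1)


@dataclass(frozen=True)
class CohortManifest:
    """Cohort table: one (subject_id, age, matrix_path) record per subject."""

    subject_ids: tuple[str, ...]
    ages: np.ndarray
    paths: tuple[str, ...]

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        ages.flags.writeable = False
        object.__setattr__(self, "ages", ages)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject_ids in manifest")
        if not (len(self.subject_ids) == ages.size == len(self.paths)):
            raise ValueError("manifest fields have unequal lengths")
        if ages.size and (not np.all(np.isfinite(ages)) or np.any(ages <= 0)):
            raise ValueError("ages must be finite and positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass(frozen=True)
class NodeTopologyProfile:
    """Per-node strength, betweenness and closeness for one connectome."""

    labels: tuple[str, ...]
    strength: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": np.arange(len(self.labels)),
                "label": list(self.labels),
                "strength": self.strength,
                "betweenness": self.betweenness,
                "closeness": self.closeness,
            }
        )


def load_connectome(
    path: str | Path, labels_path: str | Path | None = None
) -> ConnectivityMatrix:
    """Read a dense adjacency matrix from whitespace- or comma-delimited text.

    An optional non-numeric first row is treated as a header of node labels;
    a labels sidecar file (one name per line) overrides any header.
    """
    path = Path(path)
    text_rows = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not text_rows:
        raise ValueError(f"{path}: empty matrix file")
    delim = "," if "," in text_rows[0] else None
    header: list[str] | None = None
    first = text_rows[0].split(delim)
    try:
        float(first[0])
    except ValueError:
        header = [t.strip() for t in first]
        text_rows = text_rows[1:]
    w = np.array(
        [[float(t) for t in row.split(delim)] for row in text_rows], dtype=float
    )
    labels: Sequence[str] = header or ()
    if labels_path is not None:
        labels = [
            ln.strip()
            for ln in Path(labels_path).read_text().splitlines()
            if ln.strip()
        ]
    return ConnectivityMatrix(weights=w, labels=tuple(labels))


def save_connectome(C: ConnectivityMatrix, path: str | Path) -> None:
    """Write the weight matrix as comma-delimited text (full precision)."""
    np.savetxt(path, C.weights, delimiter=",", fmt="%.17g")


def average_connectomes(
    matrices: Sequence[ConnectivityMatrix],
) -> ConnectivityMatrix:
    """Elementwise arithmetic mean of same-shape connectomes."""
    if not matrices:
        raise ValueError("cannot average an empty list of matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if m.n_nodes != first.n_nodes or m.labels != first.labels:
            raise ValueError("matrices differ in size or label order")
    mean = np.mean([m.weights for m in matrices], axis=0)
    return ConnectivityMatrix(weights=mean, labels=first.labels)


def density_threshold(
    C: ConnectivityMatrix, target_density: float
) -> tuple[float, np.ndarray]:
    """Smallest threshold keeping at most the target fraction of node pairs.

    Returns ``(J_th, mask)`` where ``mask[i, j]`` is True for surviving edges
    (weight strictly greater than ``J_th``).  Ties at the threshold are
    excluded, so the retained density never exceeds the target.
    """
    if not 0.0 < target_density <= 1.0:
        raise ValueError("target_density must be in (0, 1]")
    n = C.n_nodes
    iu = np.triu_indices(n, k=1)
    upper = C.weights[iu]
    n_pairs = upper.size
    n_keep = int(np.floor(target_density * n_pairs))
    if upper.size and np.ptp(upper) == 0.0:
        warnings.warn(
            "all off-diagonal weights are equal; density target unreachable",
            RuntimeWarning,
            stacklevel=2,
        )
        keep_all = n_keep >= n_pairs and upper[0] > 0
        j_th = upper[0] - 1.0 if keep_all else upper[0]
        mask = np.zeros((n, n), dtype=bool)
        if keep_all:
            mask[iu] = True
            mask |= mask.T
        return float(j_th), mask
    order = np.sort(upper)[::-1]
    if n_keep >= n_pairs:
        j_th = order[-1] - max(1.0, abs(order[-1]))  # strictly below min
    else:
        j_th = order[n_keep]  # count of weights > order[n_keep] is <= n_keep
    mask = C.weights > j_th
    np.fill_diagonal(mask, False)
    return float(j_th), mask


def node_strength(C: ConnectivityMatrix) -> np.ndarray:
    """Per-node strength (row sums of the weight matrix)."""
    return C.strength()


def _length_graph(C: ConnectivityMatrix, binarize: bool) -> nx.Graph:
    """Graph with edge 'length' = 1/weight (or 1 if binarized)."""
    g = nx.Graph()
    g.add_nodes_from(range(C.n_nodes))
    ii, jj = np.nonzero(np.triu(C.weights, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        w = C.weights[i, j]
        g.add_edge(i, j, weight=w, length=1.0 if binarize else 1.0 / w)
    return g


def centrality_metrics(
    C: ConnectivityMatrix, binarize: bool = False
) -> NodeTopologyProfile:
    """Strength, betweenness and closeness of every node.

    Shortest paths use edge lengths ``1/weight`` — the usual convention for
    streamline-count connectomes, where heavy edges are 'short' — unless
    ``binarize`` is set, in which case all existing edges have unit length.
    Betweenness is normalized to [0, 1]; closeness uses the Wasserman–Faust
    per-component correction, so disconnected graphs are handled gracefully
    (with a warning).
    """
    g = _length_graph(C, binarize)
    if C.n_nodes and not nx.is_connected(g):
        warnings.warn(
            "graph is disconnected; closeness computed per component",
            RuntimeWarning,
            stacklevel=2,
        )
    bet = nx.betweenness_centrality(g, weight="length", normalized=True)
    clo = nx.closeness_centrality(g, distance="length", wf_improved=True)
    n = C.n_nodes
    return NodeTopologyProfile(
        labels=C.labels,
        strength=C.strength(),
        betweenness=np.array([bet[i] for i in range(n)]),
        closeness=np.array([clo[i] for i in range(n)]),
    )


def _weighted_rich_club(w: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Phi(r): for each rank r, (weight among top-r nodes) / (sum of the
    top E_r weights in the whole network), nodes ordered by strength."""
    n = w.shape[0]
    order = np.argsort(w.sum(axis=1))[::-1]
    iu = np.triu_indices(n, k=1)
    sorted_w = np.sort(w[iu])[::-1]
    cum_top = np.concatenate([[0.0], np.cumsum(sorted_w)])
    phi = np.full(ranks.size, np.nan)
    for a, r in enumerate(ranks):
        club = order[:r]
        sub = w[np.ix_(club, club)]
        e_r = int(np.count_nonzero(np.triu(sub, k=1)))
        if e_r == 0:
            continue
        phi[a] = np.triu(sub, k=1).sum() / cum_top[e_r]
    return phi


def rich_club_check(
    C: ConnectivityMatrix,
    n_null: int = 20,
    seed: int = 0,
    ranks: np.ndarray | None = None,
) -> pd.DataFrame:
    """Normalized weighted rich-club curve.

    The weighted rich-club coefficient of the top-``r``-strength nodes is
    divided by its mean over ``n_null`` topology-preserving nulls in which
    edge weights are shuffled over the existing edges.  A ratio above 1 at
    high ranks indicates that hubs concentrate the strongest connections.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    n = C.n_nodes
    if ranks is None:
        ranks = np.arange(2, n + 1)
    ranks = np.asarray(ranks, dtype=int)
    phi = _weighted_rich_club(C.weights, ranks)
    rng = np.random.default_rng(seed)
    ii, jj = np.nonzero(np.triu(C.weights, k=1))
    vals = C.weights[ii, jj]
    null_phi = np.zeros((n_null, ranks.size))
    for b in range(n_null):
        shuf = rng.permutation(vals)
        wn = np.zeros_like(C.weights)
        wn[ii, jj] = shuf
        wn += wn.T
        null_phi[b] = _weighted_rich_club(wn, ranks)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = phi / np.nanmean(null_phi, axis=0)
    return pd.DataFrame({"rank": ranks, "phi": phi, "phi_ratio": ratio})


def load_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV with header ``subject_id,age,path``."""
    df = pd.read_csv(path, dtype={"subject_id": str, "path": str})
    missing = {"subject_id", "age", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return CohortManifest(
        subject_ids=tuple(df["subject_id"]),
        ages=df["age"].to_numpy(dtype=float),
        paths=tuple(df["path"]),
    )


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": manifest.subject_ids,
            "age": manifest.ages,
            "path": manifest.paths,
        }
    ).to_csv(path, index=False)
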