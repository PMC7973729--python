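"""Pairwise distance matrices, k-medoids and silhouette validation.

Clustering works on a precomputed symmetric distance matrix so that any of
the registered string metrics can drive it.  The k-medoids variant is the
Voronoi (assign/update) iteration started from user-supplied initial medoids:
each point is assigned to its nearest medoid, then each cluster's medoid is
replaced by the member minimising the total within-cluster distance, until
the medoid set stabilises.  Medoids are actual pathways, which is the point —
a clinician can read a cluster centre as a real patient trace.

Ties are broken deterministically: a point equidistant to several medoids
joins the one with the lowest index, and a medoid-update tie keeps the lowest
point index.  Runs involve no randomness.

Silhouette scoring uses scikit-learn's implementation on the precomputed
matrix (points in singleton clusters score 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .baselines import DegenerateInputError
from .catalog import Pathway

__all__ = [
    "DistanceMatrix",
    "ClusteringResult",
    "pairwise_matrix",
    "k_medoids",
    "silhouette",
    "k_sweep",
    "read_matrix",
    "write_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal, plus row labels."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of one k-medoids run on a distance matrix."""

    medoids: tuple[int, ...]
    labels: tuple[int, ...]
    sizes: tuple[int, ...]
    iterations: int
    silhouette: float

    @property
    def k(self) -> int:
        return len(self.medoids)


def pairwise_matrix(
    pathways: Sequence["Pathway | str"],
    metric: Callable[[str, str], float],
) -> DistanceMatrix:
    """Distance matrix over a pathway list; each unordered pair is computed
    once and mirrored.  A metric degenerate-input error is re-raised naming
    the offending pathway."""
    strs = [p.codes if isinstance(p, Pathway) else p for p in pathways]
    if len(strs) < 2:
        raise ValueError("need at least two pathways")
    n = len(strs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[i, j] = values[j, i] = metric(strs[i], strs[j])
            except DegenerateInputError as exc:
                raise DegenerateInputError(
                    f"metric undefined for pathway pair ({strs[i]!r}, {strs[j]!r}): {exc}"
                ) from exc
    return DistanceMatrix(values=values, labels=tuple(strs))


def k_medoids(
    matrix: DistanceMatrix,
    initial_medoids: Sequence[int],
    max_iter: int = 100,
) -> ClusteringResult:
    """Voronoi-iteration k-medoids from fixed initial medoids.

    Alternates assignment and medoid update until the medoid set is stable or
    ``max_iter`` is reached.  The total within-cluster distance to medoids is
    non-increasing across iterations.
    """
    k = len(initial_medoids)
    n = matrix.n
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    if len(set(initial_medoids)) != k:
        raise ValueError("initial medoids must be distinct")
    if any(i < 0 or i >= n for i in initial_medoids):
        raise ValueError("initial medoid index out of range")

    values = matrix.values
    medoids = np.sort(np.asarray(initial_medoids, dtype=int))
    iterations = 0
    prev_cost = np.inf
    for _ in range(max_iter):
        iterations += 1
        labels = np.argmin(values[:, medoids], axis=1)
        labels[medoids] = np.arange(k)  # a medoid always belongs to its own cluster
        cost = float(values[np.arange(n), medoids[labels]].sum())
        assert cost <= prev_cost + 1e-12, "within-cluster cost increased"
        prev_cost = cost
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            totals = values[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(totals))]  # first min = lowest index
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids

    labels = np.argmin(values[:, medoids], axis=1)
    labels[medoids] = np.arange(k)
    sizes = tuple(int((labels == c).sum()) for c in range(k))
    sil = silhouette(matrix, labels) if k >= 2 else 0.0
    return ClusteringResult(
        medoids=tuple(int(m) for m in medoids),
        labels=tuple(int(l) for l in labels),
        sizes=sizes,
        iterations=iterations,
        silhouette=sil,
    )


def silhouette(matrix: DistanceMatrix, labels: Sequence[int]) -> float:
    """Mean silhouette coefficient ``(b - a) / max(a, b)`` over all points.

    ``a`` is a point's mean distance to its own cluster (excluding itself)
    and ``b`` the smallest mean distance to any other cluster; points in
    singleton clusters score 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    if len(uniq) == len(labels):
        return 0.0  # every cluster a singleton
    return float(silhouette_score(matrix.values, labels, metric="precomputed"))


def k_sweep(
    matrix: DistanceMatrix,
    k_range: Sequence[int],
    initial_medoids_per_k: dict[int, Sequence[int]] | None = None,
    max_iter: int = 100,
) -> list[tuple[int, ClusteringResult]]:
    """Run k-medoids for each k and rank the results by silhouette (best first).

    Initial medoids default to points ``0 .. k-1`` for each k when no mapping
    is supplied.
    """
    results = []
    for k in k_range:
        if not 2 <= k <= matrix.n - 1:
            raise ValueError(f"k={k} outside the valid range [2, {matrix.n - 1}]")
        init = (
            initial_medoids_per_k[k]
            if initial_medoids_per_k is not None
            else list(range(k))
        )
        results.append((k, k_medoids(matrix, init, max_iter=max_iter)))
    return sorted(results, key=lambda kr: -kr[1].silhouette)


def write_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a square CSV with pathway labels as header row and column."""
    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(path)


def read_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(values=df.to_numpy(dtype=float), labels=tuple(str(c) for c in df.columns))
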