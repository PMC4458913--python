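"""FLAME fuzzy clustering, cluster purity, and the Rand index.

FLAME (Fuzzy clustering by Local Approximation of MEmberships) clusters
objects from a similarity matrix without a preset cluster count:

1. distance = 1 - similarity; each object gets its k nearest neighbors and
   a density (reciprocal of the mean distance to those neighbors);
2. objects denser than all of their neighbors become cluster-supporting
   objects (CSOs), each seeding one cluster; objects below a density
   threshold that are also less dense than all their neighbors become
   outliers;
3. every other object's fuzzy membership vector is iteratively replaced by
   a distance-weighted average of its neighbors' vectors (CSO and outlier
   vectors stay fixed) until the update converges;
4. hard labels are the argmax of the converged vectors.

All orderings (neighbor selection under distance ties, density ties for
CSO election) are broken by object identifier ascending, so a rerun on the
same matrix reproduces the same clustering exactly.

Purity compares a hard clustering with a category map: each cluster's
majority category M is the category carried by the largest number of
members, and purity is the fraction of members carrying M.  The Rand index
compares two hard partitions as the fraction of object pairs treated
consistently (co-clustered in both, or separated in both).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "FlameResult",
    "PartitionComparison",
    "OUTLIER_LABEL",
    "flame_cluster",
    "hard_clusters",
    "cluster_purity",
    "rand_index",
    "categories_to_partition",
    "write_clustering_tsv",
]

OUTLIER_LABEL = -1


@dataclass(frozen=True)
class FlameResult:
    object_ids: tuple[str, ...]
    memberships: np.ndarray  # objects × (clusters + 1 outlier column)
    cluster_of: dict[str, int]  # hard labels; OUTLIER_LABEL for the outlier group
    csos: frozenset[str]
    outliers: frozenset[str]

    @property
    def n_clusters(self) -> int:
        return self.memberships.shape[1] - 1

    def membership_of(self, object_id: str) -> np.ndarray:
        return self.memberships[self.object_ids.index(object_id)]


@dataclass(frozen=True)
class PartitionComparison:
    same_same: int  # pairs co-clustered in both partitions (x)
    diff_diff: int  # pairs separated in both partitions (y)
    n: int

    @property
    def rand(self) -> float:
        return (self.same_same + self.diff_diff) / comb(self.n, 2)


def _denser(density: np.ndarray, i: int, j: int) -> bool:
    """Total order on objects: density descending, index (identifier) ascending."""
    if density[i] != density[j]:
        return density[i] > density[j]
    return i < j


def flame_cluster(
    similarity: SimilarityMatrix,
    k: int = 10,
    outlier_threshold: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> FlameResult:
    """Cluster a square symmetric similarity matrix with FLAME.

    Parameters
    ----------
    k
        Neighborhood size; must satisfy 1 <= k < number of objects.
    outlier_threshold
        Density below which a local density minimum is declared an outlier.
        Defaults to mean density minus two standard deviations.
    max_iter, tol
        Stopping rule for the membership iteration: stop when the largest
        membership change falls below ``tol`` or after ``max_iter`` sweeps.
    """
    if not similarity.is_square:
        raise ValueError("FLAME needs a square matrix")
    values = similarity.values
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("FLAME needs a symmetric matrix")
    n = len(similarity.row_ids)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}, got {k}")

    # object order follows identifier order so index ties == identifier ties
    order = np.argsort(np.array(similarity.row_ids))
    ids = tuple(similarity.row_ids[i] for i in order)
    dist = 1.0 - values[np.ix_(order, order)]

    # k nearest neighbors, distance ties broken by identifier
    knn = np.empty((n, k), dtype=int)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        others.sort(key=lambda j: (dist[i, j], j))
        knn[i] = others[:k]

    mean_dist = dist[np.arange(n)[:, None], knn].mean(axis=1)
    with np.errstate(divide="ignore"):
        density = np.where(mean_dist > 0, 1.0 / np.maximum(mean_dist, 1e-300), np.inf)
    if outlier_threshold is None:
        finite = density[np.isfinite(density)]
        if finite.size:
            outlier_threshold = float(finite.mean() - 2 * finite.std())
        else:
            outlier_threshold = -np.inf

    cso_idx = [
        i for i in range(n) if all(_denser(density, i, j) for j in knn[i])
    ]
    outlier_idx = [
        i
        for i in range(n)
        if i not in cso_idx
        and density[i] < outlier_threshold
        and all(_denser(density, j, i) for j in knn[i])
    ]
    cso_set = set(cso_idx)
    outlier_set = set(outlier_idx)

    n_clusters = len(cso_idx)
    n_cols = n_clusters + 1  # trailing outlier column
    memb = np.full((n, n_cols), 1.0 / n_cols)
    for c, i in enumerate(cso_idx):
        memb[i] = 0.0
        memb[i, c] = 1.0
    for i in outlier_idx:
        memb[i] = 0.0
        memb[i, -1] = 1.0

    # neighbor weights: w_ij proportional to (cutoff_i - d_ij), cutoff_i being
    # the distance to the farthest neighbor; degenerate all-equal neighborhoods
    # fall back to uniform weights
    weights = np.empty((n, k))
    for i in range(n):
        d = dist[i, knn[i]]
        w = np.maximum(0.0, d.max() - d)
        s = w.sum()
        weights[i] = w / s if s > 0 else np.full(k, 1.0 / k)

    free = [i for i in range(n) if i not in cso_set and i not in outlier_set]
    for _ in range(max_iter):
        new = memb.copy()
        for i in free:
            new[i] = weights[i] @ memb[knn[i]]
        delta = np.abs(new - memb).max()
        memb = new
        if delta < tol:
            break

    cluster_of: dict[str, int] = {}
    for i, oid in enumerate(ids):
        col = int(np.argmax(memb[i]))
        cluster_of[oid] = OUTLIER_LABEL if col == n_cols - 1 else col
    return FlameResult(
        object_ids=ids,
        memberships=memb,
        cluster_of=cluster_of,
        csos=frozenset(ids[i] for i in cso_idx),
        outliers=frozenset(ids[i] for i in outlier_idx),
    )


def hard_clusters(
    result: FlameResult, include_outliers: bool = False
) -> dict[int, set[str]]:
    """Group objects by hard label; the outlier group is dropped by default."""
    clusters: dict[int, set[str]] = {}
    for oid, label in result.cluster_of.items():
        if label == OUTLIER_LABEL and not include_outliers:
            continue
        clusters.setdefault(label, set()).add(oid)
    return clusters


def cluster_purity(
    clusters: Mapping[Hashable, set[str]],
    categories: Mapping[str, set[str]],
) -> tuple[dict[Hashable, float], float]:
    """Majority-category purity per cluster and its arithmetic mean.

    For each cluster the majority category M maximizes the number of members
    whose category set contains it (ties broken by category name); purity is
    the fraction of members containing M.  Empty clusters are excluded with
    a warning.
    """
    per_cluster: dict[Hashable, float] = {}
    for label in sorted(clusters, key=str):
        members = clusters[label]
        if not members:
            warnings.warn(f"cluster {label!r} is empty; excluded from purity")
            continue
        counts: dict[str, int] = {}
        for member in members:
            for cat in categories[member]:
                counts[cat] = counts.get(cat, 0) + 1
        if not counts:
            warnings.warn(f"cluster {label!r} has no categorized member; excluded")
            continue
        majority = max(sorted(counts), key=lambda c: counts[c])
        per_cluster[label] = counts[majority] / len(members)
    if not per_cluster:
        raise ValueError("no non-empty cluster to evaluate")
    average = sum(per_cluster.values()) / len(per_cluster)
    return per_cluster, average


def rand_index(
    clustering_a: Mapping[str, Hashable],
    clustering_b: Mapping[str, Hashable],
) -> PartitionComparison:
    """Agreement between two hard partitions over the same objects."""
    if clustering_a.keys() != clustering_b.keys():
        raise ValueError("partitions cover different object universes")
    objects = sorted(clustering_a)
    n = len(objects)
    if n < 2:
        raise ValueError("Rand index needs at least 2 objects")
    x = y = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = clustering_a[objects[i]] == clustering_a[objects[j]]
            same_b = clustering_b[objects[i]] == clustering_b[objects[j]]
            if same_a and same_b:
                x += 1
            elif not same_a and not same_b:
                y += 1
    return PartitionComparison(same_same=x, diff_diff=y, n=n)


def categories_to_partition(
    categories: Mapping[str, set[str]],
    multi_label: str = "exclude",
) -> dict[str, str]:
    """Project a (possibly multi-valued) category map onto a hard partition.

    ``multi_label='exclude'`` drops diseases with more than one category
    (the default — a partition needs single labels); ``'first'`` keeps the
    lexicographically first category instead.
    """
    if multi_label not in ("exclude", "first"):
        raise ValueError("multi_label must be 'exclude' or 'first'")
    partition: dict[str, str] = {}
    for disease, cats in categories.items():
        if not cats:
            continue
        if len(cats) == 1 or multi_label == "first":
            partition[disease] = min(cats)
    return partition


def write_clustering_tsv(result: FlameResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("object_id\tcluster_label\tmax_membership\n")
        for i, oid in enumerate(result.object_ids):
            fh.write(
                f"{oid}\t{result.cluster_of[oid]}\t{result.memberships[i].max():.10g}\n"
            )
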