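"""Herb feature profiles and Ward (minimum-variance) hierarchical clustering.

Herbs are described at several levels — clinical symptoms, protein targets, GO
terms, KEGG pathways — as incidence profiles: binary membership for symptom
and target levels, enriched-gene counts for the pathway levels. Profiles are
compared by Euclidean distance and clustered agglomeratively under Ward's
criterion: at each step the pair of clusters whose merge least increases the
total within-cluster error sum of squares

    ESS(C) = sum_i x_i^2 - (sum_i x_i)^2 / n      (per coordinate, summed)

is joined. For clusters A, B with sizes n_A, n_B and centroids c_A, c_B the
increase is the closed form n_A n_B / (n_A + n_B) * ||c_A - c_B||^2 (d^2 / 2
for two singletons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FeatureProfile",
    "ClusterState",
    "build_profile",
    "euclidean",
    "ess",
    "ward_cluster",
    "multilevel_summary",
]

LEVELS = ("symptom", "target", "go", "kegg")


@dataclass(frozen=True)
class FeatureProfile:
    """Herb x feature incidence matrix (0/1 membership or counts)."""

    herbs: tuple[str, ...]
    features: tuple[str, ...]
    matrix: np.ndarray
    level: str

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.herbs), len(self.features)):
            raise ValueError("matrix shape does not match label lengths")
        if (self.matrix.sum(axis=1) == 0).any():
            raise ValueError("profiles must not contain all-zero rows")


def build_profile(
    herb_features: Mapping[str, object],
    level: str = "symptom",
) -> FeatureProfile:
    """Build a profile from herb → feature-set (binary) or feature → count maps.

    Columns are the union of all features, sorted lexicographically. Herbs with
    no features are dropped with a warning; at least two herbs must remain.
    """
    counted: dict[str, Mapping[str, float]] = {}
    for herb, feats in herb_features.items():
        if isinstance(feats, Mapping):
            counted[herb] = {f: float(v) for f, v in feats.items() if v}
        else:
            counted[herb] = {f: 1.0 for f in feats}
    empty = sorted(h for h, d in counted.items() if not d)
    if empty:
        warnings.warn(f"dropping herbs with empty feature sets: {empty}", stacklevel=2)
        for h in empty:
            del counted[h]
    if len(counted) < 2:
        raise ValueError("need at least two herbs with non-empty feature sets")
    herbs = tuple(sorted(counted))
    features = tuple(sorted(set().union(*(d.keys() for d in counted.values()))))
    index = {f: j for j, f in enumerate(features)}
    mat = np.zeros((len(herbs), len(features)))
    for i, h in enumerate(herbs):
        for f, v in counted[h].items():
            mat[i, index[f]] = v
    return FeatureProfile(herbs, features, mat, level)


def euclidean(profile: FeatureProfile | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix between herb rows."""
    X = profile.matrix if isinstance(profile, FeatureProfile) else np.asarray(profile, float)
    return squareform(pdist(X, metric="euclidean"))


def ess(points: np.ndarray) -> float:
    """Error sum of squares of a point cloud, per coordinate and summed."""
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    return float((X**2).sum() - (X.sum(axis=0) ** 2).sum() / n)


@dataclass(frozen=True)
class ClusterState:
    """Ward merge tree over labelled items.

    ``merges`` records, oldest first, the two cluster labels joined (each label
    is the sorted tuple of its members) and the ESS increase of that merge;
    ``heights`` is the cumulative total ESS after each merge, which is
    non-decreasing because every merge cost is non-negative.
    """

    items: tuple[str, ...]
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]
    heights: tuple[float, ...]

    def assignment(self, k: int) -> dict[str, int]:
        """Flat clustering with ``k`` clusters: herb → label in 1..k.

        Labels are assigned in order of each cluster's lexicographically
        smallest member, so the output is deterministic.
        """
        n = len(self.items)
        if not 1 <= k <= n:
            raise ValueError(f"k must lie in [1, {n}]")
        clusters: list[set[str]] = [{it} for it in self.items]
        for a, b, _ in self.merges[: n - k]:
            sa, sb = set(a), set(b)
            clusters = [c for c in clusters if c != sa and c != sb]
            clusters.append(sa | sb)
        clusters.sort(key=lambda c: min(c))
        out: dict[str, int] = {}
        for label, members in enumerate(clusters, start=1):
            for it in members:
                out[it] = label
        return out


def ward_cluster(
    profile: FeatureProfile | np.ndarray,
    labels: Sequence[str] | None = None,
) -> ClusterState:
    """Agglomerate by minimum ESS increase down to a single cluster.

    Ties in merge cost are broken by the lexicographically smallest pair of
    cluster labels (a label is the sorted tuple of member names), making the
    tree deterministic under row permutations up to identical coordinates.
    """
    if isinstance(profile, FeatureProfile):
        X = profile.matrix.astype(float)
        names = list(profile.herbs)
    else:
        X = np.asarray(profile, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(labels) if labels is not None else [str(i) for i in range(len(X))]
    n = len(names)
    if n < 2:
        raise ValueError("need at least two items to cluster")

    members: list[tuple[str, ...]] = [(nm,) for nm in names]
    sizes = [1.0] * n
    centroids = [X[i].copy() for i in range(n)]
    total = 0.0
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    heights: list[float] = []
    while len(members) > 1:
        best: tuple[float, tuple[tuple[str, ...], tuple[str, ...]], int, int] | None = None
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                diff = centroids[i] - centroids[j]
                delta = sizes[i] * sizes[j] / (sizes[i] + sizes[j]) * float(diff @ diff)
                pair = tuple(sorted((members[i], members[j])))
                cand = (delta, pair, i, j)
                if best is None or (delta, pair) < (best[0], best[1]):
                    best = cand
        delta, pair, i, j = best
        merged = tuple(sorted(members[i] + members[j]))
        new_size = sizes[i] + sizes[j]
        new_centroid = (sizes[i] * centroids[i] + sizes[j] * centroids[j]) / new_size
        total += delta
        merges.append((pair[0], pair[1], delta))
        heights.append(total)
        for idx in sorted((i, j), reverse=True):
            del members[idx], sizes[idx], centroids[idx]
        members.append(merged)
        sizes.append(new_size)
        centroids.append(new_centroid)
    return ClusterState(tuple(names), tuple(merges), tuple(heights))


def multilevel_summary(assignments: Mapping[str, Mapping[str, int]]):
    """Cross-level cluster table: rows are cluster indices, columns are levels.

    Each cell lists the member herbs of that cluster at that level
    (comma-joined, sorted); absent clusters show an em dash.
    """
    import pandas as pd

    levels = list(assignments)
    k_max = max((max(a.values()) for a in assignments.values() if a), default=0)
    data: dict[str, list[str]] = {}
    for level in levels:
        col: list[str] = []
        by_cluster: dict[int, list[str]] = {}
        for herb, c in assignments[level].items():
            by_cluster.setdefault(c, []).append(herb)
        for c in range(1, k_max + 1):
            col.append(", ".join(sorted(by_cluster.get(c, []))) or "—")
        data[level] = col
    return pd.DataFrame(data, index=pd.RangeIndex(1, k_max + 1, name="cluster"))
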