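"""Unsupervised hierarchical clustering of samples over a miRNA signature:
Pearson-correlation distance with average linkage (UPGMA).

UPGMA is implemented directly rather than delegated so the tie-break is
fully specified: among all cluster pairs at the minimal mean inter-cluster
distance, the pair whose sorted leaf-id representations are
lexicographically smallest merges first. This makes the dendrogram
invariant to the input order of samples, which matters for reproducible
cluster reads on real cohorts where distance ties do occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import ExpressionMatrix, SampleAnnotation, Stage, annotations_to_frame


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: the two clusters (as sorted leaf tuples)
    and the mean inter-cluster distance at which they merged."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass(frozen=True)
class Dendrogram:
    leaf_ids: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaf_ids) - 1:
            raise ValidationError(
                f"{len(self.leaf_ids)} leaves require {len(self.leaf_ids) - 1} merges, "
                f"got {len(self.merges)}"
            )


def pearson_distance(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise sample distance d(i, j) = 1 - Pearson r of the two samples'
    feature vectors; symmetric, zero diagonal, values in [0, 2]."""
    matrix.require_stage(Stage.STANDARDIZED)
    values = matrix.values
    sds = values.std(axis=0)
    dead = [s for s, sd in zip(matrix.sample_ids, sds) if sd == 0]
    if dead:
        raise ValidationError(f"zero-variance sample vector(s): {dead}")
    corr = np.corrcoef(values, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(dist, index=matrix.sample_ids, columns=matrix.sample_ids)


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA on a symmetric distance grid.

    At each step the pair of clusters with minimal mean inter-cluster
    distance merges; the new cluster's distances to the others are
    size-weighted means, which keeps every active distance equal to the
    mean of the original leaf-to-leaf distances across the two clusters.
    """
    if dist.shape[0] != dist.shape[1] or not (dist.index == dist.columns).all():
        raise ValidationError("distance grid must be square with matching labels")
    if dist.shape[0] < 2:
        raise ValidationError("need at least two samples to cluster")
    leaves = [str(s) for s in dist.index]
    d = {
        frozenset((a, b)): float(dist.iloc[i, j])
        for i, a in enumerate(leaves)
        for j, b in enumerate(leaves)
        if i < j
    }
    clusters: dict[tuple[str, ...], int] = {(leaf,): 1 for leaf in leaves}
    key = {(leaf,): leaf for leaf in leaves}  # cluster -> dict key in d (leaf-set repr)

    def pair_dist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        total = 0.0
        for x in a:
            for y in b:
                total += d[frozenset((x, y))]
        return total / (len(a) * len(b))

    # cache of current inter-cluster distances, maintained incrementally
    active = {
        tuple(sorted((ca, cb))): pair_dist(ca, cb)
        for i, ca in enumerate(clusters)
        for j, cb in enumerate(clusters)
        if i < j
    }
    merges: list[Merge] = []
    while len(clusters) > 1:
        best = min(active.items(), key=lambda kv: (kv[1], kv[0]))
        (ca, cb), height = best
        merged = tuple(sorted(ca + cb))
        na, nb = clusters.pop(ca), clusters.pop(cb)
        for pair in [p for p in active if ca in p or cb in p]:
            del active[pair]
        for other, n_other in clusters.items():
            da = pair_dist(ca, other)
            db = pair_dist(cb, other)
            new = (na * da + nb * db) / (na + nb)
            active[tuple(sorted((merged, other)))] = new
        clusters[merged] = na + nb
        merges.append(Merge(left=min(ca, cb), right=max(ca, cb), height=height))
    return Dendrogram(leaf_ids=tuple(sorted(leaves)), merges=tuple(merges))


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Partition leaves into k clusters by discarding the k-1 highest merges.

    Merge heights are non-decreasing under average linkage, so replaying
    the first n-k merges yields the cut. Labels are 0..k-1 in order of each
    cluster's smallest member id.
    """
    n = len(dendrogram.leaf_ids)
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    parent: dict[str, str] = {leaf: leaf for leaf in dendrogram.leaf_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for merge in dendrogram.merges[: n - k]:
        ra, rb = find(merge.left[0]), find(merge.right[0])
        parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for leaf in dendrogram.leaf_ids:
        groups.setdefault(find(leaf), []).append(leaf)
    labels: dict[str, int] = {}
    for label, root in enumerate(sorted(groups, key=lambda r: min(groups[r]))):
        for leaf in groups[root]:
            labels[leaf] = label
    return labels


def cluster_composition(
    labels: Mapping[str, int], annotations: Sequence[SampleAnnotation]
) -> pd.DataFrame:
    """Contingency of cluster x truth group with per-cluster size, purity
    and majority group."""
    ann = annotations_to_frame(annotations)
    rows = []
    for sample, label in labels.items():
        if sample not in ann.index:
            raise ValidationError(f"sample {sample!r} has no annotation")
        rows.append({"cluster": label, "group": ann.loc[sample, "group"]})
    table = pd.crosstab(
        pd.Series([r["cluster"] for r in rows], name="cluster"),
        pd.Series([r["group"] for r in rows], name="group"),
    )
    table["size"] = table.sum(axis=1)
    counts = table.drop(columns="size")
    table["majority_group"] = counts.idxmax(axis=1)
    table["purity"] = counts.max(axis=1) / table["size"]
    return table


def export_newick(dendrogram: Dendrogram) -> str:
    """Serialise the dendrogram as a Newick string; branch lengths are the
    height gaps between a node and its parent merge (leaves sit at 0)."""
    height_of: dict[tuple[str, ...], float] = {(leaf,): 0.0 for leaf in dendrogram.leaf_ids}
    text_of: dict[tuple[str, ...], str] = {(leaf,): leaf for leaf in dendrogram.leaf_ids}
    last: tuple[str, ...] = dendrogram.leaf_ids and (dendrogram.leaf_ids[0],)
    for merge in dendrogram.merges:
        for child in (merge.left, merge.right):
            if child not in text_of:
                raise ValidationError(f"merge references unknown cluster {child}")
        bl_left = merge.height - height_of[merge.left]
        bl_right = merge.height - height_of[merge.right]
        node = merge.members
        text_of[node] = (
            f"({text_of[merge.left]}:{bl_left:.10g},{text_of[merge.right]}:{bl_right:.10g})"
        )
        height_of[node] = merge.height
        last = node
    return text_of[last] + ";"


class SignatureClusterer:
    """sklearn-style clusterer: Pearson distance + UPGMA + k-cut.

    Parameters
    ----------
    n_clusters : int, default 2
        Number of clusters read off the dendrogram.

    Attributes
    ----------
    dendrogram_ : Dendrogram
    labels_ : ndarray of cluster labels aligned with the fitted matrix's
        sample order
    distance_ : DataFrame of pairwise distances
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValidationError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: ExpressionMatrix, y=None):
        self.distance_ = pearson_distance(X)
        self.dendrogram_ = average_linkage(self.distance_)
        mapping = cut_clusters(self.dendrogram_, self.n_clusters)
        self.label_map_ = mapping
        self.labels_ = np.array([mapping[s] for s in X.sample_ids])
        return self

    def fit_predict(self, X: ExpressionMatrix, y=None) -> np.ndarray:
        return self.fit(X).labels_
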