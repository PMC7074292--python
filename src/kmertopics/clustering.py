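"""Hierarchical clustering of genomes and agreement with taxonomy.

Genomes are clustered on their document-topic distributions (or any pairwise
distance); the tree is exported as Newick and flat cuts are scored against
family labels by purity and the adjusted Rand index.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import jensenshannon, pdist, squareform
from scipy.special import comb

METRICS = ("euclidean", "jensen-shannon")
LINKAGES = ("average", "complete", "ward")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.d = d


@dataclass
class ClusterTree:
    """Agglomerative merge tree: SciPy linkage matrix plus leaf labels."""

    ids: list[str]
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.ids)


def topic_distance_matrix(
    theta: np.ndarray,
    ids: Sequence[str],
    metric: str = "euclidean",
) -> DistanceMatrix:
    """Pairwise distances between document-topic distributions.

    ``jensen-shannon`` is the JS divergence in bits (square of SciPy's
    base-2 JS distance).
    """
    theta = np.asarray(theta, dtype=float)
    if metric == "euclidean":
        d = squareform(pdist(theta, metric="euclidean"))
    elif metric == "jensen-shannon":
        d = squareform(pdist(theta, metric=lambda p, q: jensenshannon(p, q, base=2) ** 2))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(ids), d=d)


def hierarchical_cluster(D: DistanceMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of a distance matrix (average/complete/ward)."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    Z = sch.linkage(squareform(D.d, checks=False), method=linkage)
    return ClusterTree(ids=list(D.ids), linkage=Z)


def cut_tree(tree: ClusterTree, n_clusters: int) -> dict[str, int]:
    """Flat clustering obtained by removing the n_clusters - 1 highest merges."""
    n = tree.n_leaves
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters={n_clusters} outside [1, {n}]")
    labels = sch.cut_tree(tree.linkage, n_clusters=n_clusters).ravel()
    return {doc_id: int(lab) for doc_id, lab in zip(tree.ids, labels)}


@dataclass
class Agreement:
    purity: float
    adjusted_rand_index: float
    misplaced: list[str]


def adjusted_rand_index(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """ARI under the permutation model, from the contingency table.

    ARI = (sum_ij C(n_ij,2) - E) / (max - E) with
    E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2).
    """
    a_vals, a_inv = np.unique(labels_a, return_inverse=True)
    b_vals, b_inv = np.unique(labels_b, return_inverse=True)
    n = len(a_inv)
    table = np.zeros((len(a_vals), len(b_vals)), dtype=np.int64)
    np.add.at(table, (a_inv, b_inv), 1)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0  # both partitions trivial
    return float((sum_ij - expected) / (max_index - expected))


def agreement(
    labels: Mapping[str, int], families: Mapping[str, str]
) -> Agreement:
    """Score a flat clustering against family labels.

    Purity is the fraction of genomes whose cluster's majority family equals
    their own; ``misplaced`` lists the violators.
    """
    if set(labels) != set(families):
        raise ValueError("cluster labels and family labels cover different genomes")
    ids = sorted(labels)
    clus = [labels[i] for i in ids]
    fams = [families[i] for i in ids]
    majority: dict[int, str] = {}
    for c in set(clus):
        members = [f for cc, f in zip(clus, fams) if cc == c]
        # deterministic tie-break: lexicographically smallest majority family
        best = max(sorted(set(members)), key=members.count)
        majority[c] = best
    misplaced = [i for i, c, f in zip(ids, clus, fams) if majority[c] != f]
    fam_codes = {f: i for i, f in enumerate(sorted(set(fams)))}
    ari = adjusted_rand_index(clus, [fam_codes[f] for f in fams])
    return Agreement(
        purity=1.0 - len(misplaced) / len(ids),
        adjusted_rand_index=ari,
        misplaced=misplaced,
    )


def to_newick(tree: ClusterTree) -> str:
    """Newick string with branch lengths from merge heights (leaves at height 0)."""
    Z = tree.linkage
    n = tree.n_leaves
    if n == 1:
        return f"{tree.ids[0]}:0.0;"
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return tree.ids[node]
        left, right, height = int(Z[node - n, 0]), int(Z[node - n, 1]), Z[node - n, 2]
        heights[node] = height
        parts = []
        for child in (left, right):
            sub = render(child)
            parts.append(f"{sub}:{height - heights[child]:.10g}")
        return "(" + ",".join(parts) + ")"

    return render(2 * n - 2) + ";"
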