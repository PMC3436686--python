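"""Pairwise pathway gene-set similarity and its clustered ordering."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .model import PathwayRecord


def jaccard_index(genes_i: frozenset[str] | set[str], genes_j: frozenset[str] | set[str]) -> float:
    """|i ∩ j| / |i ∪ j| for two non-empty gene sets."""
    if not genes_i or not genes_j:
        raise ValueError("jaccard_index requires non-empty sets")
    inter = len(genes_i & genes_j)
    union = len(genes_i) + len(genes_j) - inter
    return inter / union


@dataclass
class SimilarityMatrix:
    pathway_keys: list[tuple[str, str]]
    values: np.ndarray
    leaf_order: list[int] = field(default_factory=list)

    def validate(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.pathway_keys):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0,1]")


def _ordered_leaves(linkage: np.ndarray, n: int) -> list[int]:
    """Dendrogram leaf order with the lower-index subtree always first."""
    children: dict[int, tuple[int, int]] = {}
    min_leaf = list(range(n))
    for k, row in enumerate(linkage):
        a, b = int(row[0]), int(row[1])
        children[n + k] = (a, b)
        min_leaf.append(min(min_leaf[a], min_leaf[b]))
    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = children[node]
        first, second = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        stack.append(second)
        stack.append(first)
    return order


def cluster_order(values: np.ndarray) -> list[int]:
    """Leaf order from average-linkage clustering on distance 1 - J.

    Deterministic: scipy breaks distance ties by condensed-matrix position
    and subtrees are emitted lower original index first, so an all-equal
    off-diagonal matrix keeps the input order.
    """
    n = values.shape[0]
    if n <= 2:
        return list(range(n))
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return _ordered_leaves(linkage, n)


def similarity_matrix(pathways: Sequence[PathwayRecord]) -> SimilarityMatrix:
    """All-pairs Jaccard matrix over database-scoped pathways, clustered."""
    if len(pathways) < 2:
        raise ValueError("need at least 2 pathways")
    n = len(pathways)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard_index(pathways[i].genes, pathways[j].genes)
    result = SimilarityMatrix(
        pathway_keys=[pw.key for pw in pathways],
        values=values,
        leaf_order=cluster_order(values),
    )
    result.validate()
    return result


def expected_jaccard(universe_size: int, size_i: int, size_j: int) -> float:
    """E[J] for two uniformly random subsets of fixed sizes (analytic).

    The intersection size is hypergeometric; the expectation sums
    k/(a+b-k) over its pmf.
    """
    from scipy.stats import hypergeom

    ks = np.arange(0, min(size_i, size_j) + 1)
    pmf = hypergeom.pmf(ks, universe_size, size_i, size_j)
    return float(np.sum(pmf * ks / (size_i + size_j - ks)))
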