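"""Hierarchical clustering of factors (average linkage, Euclidean distance).

Factors — not subjects — are the objects being clustered: each factor is its
length-N column vector in the standardized cohort, so the Euclidean distance
between two factors is a monotone function of their Pearson correlation,
d^2 = 2 (N-1) (1 - r). Inter-cluster distance is the average of all pairwise
member distances (UPGMA), which is monotone: merge heights never decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .clustering import FactorClustering, clustering_from_labels
from .cohort_io import NormalizedMatrix
from .exceptions import ConfigError


@dataclass
class FactorDistanceMatrix:
    """F x F symmetric Euclidean distances between factor column vectors."""

    values: np.ndarray
    factor_names: list[str]

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class Dendrogram:
    """Agglomerative merge history in SciPy linkage form.

    ``merges`` is the (F-1) x 4 linkage matrix: each row is (left node,
    right node, merge height, member count), with nodes < F being leaves.
    """

    merges: np.ndarray
    leaf_names: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def factor_distances(matrix: NormalizedMatrix) -> FactorDistanceMatrix:
    """Pairwise Euclidean distances between factor columns."""
    dm = squareform(pdist(matrix.values.T, metric="euclidean"))
    return FactorDistanceMatrix(values=dm, factor_names=list(matrix.factor_names))


def average_linkage_tree(dist: FactorDistanceMatrix) -> Dendrogram:
    """UPGMA tree: the distance between clusters w and v is the mean of all
    |w| x |v| pairwise leaf distances."""
    if dist.n_factors < 2:
        raise ConfigError("need at least 2 factors to build a tree")
    Z = hierarchy.linkage(dist.condensed(), method="average")
    return Dendrogram(merges=Z, leaf_names=list(dist.factor_names))


def cut_tree(tree: Dendrogram, k: int) -> FactorClustering:
    """Flat clusters obtained by undoing the last k-1 merges."""
    if not 1 <= k <= tree.n_leaves:
        raise ConfigError(f"k must be in [1, {tree.n_leaves}], got {k}")
    labels = hierarchy.cut_tree(tree.merges, n_clusters=k).ravel()
    return clustering_from_labels("HCA", tree.leaf_names, labels, {"k": k, "linkage": "average"})


def _newick_label(name: str) -> str:
    # underscores must be quoted too: unquoted "_" reads back as a space
    if any(ch in name for ch in " _\t(),:;'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string.

    Branch lengths follow the ultrametric convention: every node sits at half
    its merge height, so each leaf is at distance (root height)/2 from the
    root and a two-leaf tree merged at height 2 renders as ``(A:1.0,B:1.0);``.
    """
    f = tree.n_leaves
    heights = {i: 0.0 for i in range(f)}
    for row_idx, (a, b, h, _cnt) in enumerate(tree.merges):
        heights[f + row_idx] = float(h)

    def render(node: int, parent_height: float) -> str:
        length = (parent_height - heights[node]) / 2.0
        if node < f:
            return f"{_newick_label(tree.leaf_names[node])}:{length:g}"
        a, b = int(tree.merges[node - f, 0]), int(tree.merges[node - f, 1])
        return f"({render(a, heights[node])},{render(b, heights[node])}):{length:g}"

    root = f + tree.merges.shape[0] - 1
    a, b = int(tree.merges[-1, 0]), int(tree.merges[-1, 1])
    body = f"({render(a, heights[root])},{render(b, heights[root])})"
    return body + ";"
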