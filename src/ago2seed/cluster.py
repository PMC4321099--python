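"""Unsupervised hierarchical clustering of expression profiles.

Average-linkage (UPGMA) agglomeration on Pearson correlation distance
d = 1 - r, the standard grouping used to separate genotype/timepoint
profiles of differentially expressed miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .arrays import ExpressionMatrix


def pearson_distance(matrix: ExpressionMatrix | pd.DataFrame,
                     axis: str = "features") -> pd.DataFrame:
    """Pairwise Pearson correlation distance, d(i, j) = 1 - r(i, j).

    ``axis='features'`` compares rows; ``axis='samples'`` compares columns.
    Symmetric with a zero diagonal, values in [0, 2].  A zero-variance
    vector has no defined correlation and raises an error naming it.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if axis == "samples":
        values = values.T
    elif axis != "features":
        raise ValueError(f"unknown axis {axis!r}")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 vectors to compute distances")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    flat = values.index[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance vector(s): {', '.join(map(str, flat[:5]))}")
    r = np.corrcoef(arr)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # enforce exact symmetry
    return pd.DataFrame(d, index=values.index, columns=values.index)


@dataclass
class Dendrogram:
    """UPGMA merge tree over labeled leaves.

    ``merges`` is the scipy linkage matrix: row k merges nodes ``merges[k,0]``
    and ``merges[k,1]`` (indices < n are leaves) at height ``merges[k,2]``.
    """

    merges: np.ndarray
    labels: list[str]
    metric: str = "pearson"
    linkage: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster assignment with ``k`` clusters."""
        flat = hierarchy.fcluster(self.merges, k, criterion="maxclust")
        return dict(zip(self.labels, map(int, flat)))

    def to_newick(self) -> str:
        """Newick export; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.merges)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        inner = ",".join(render(child, root.dist)
                         for child in (root.left, root.right))
        return f"({inner});"

    def plot(self, ax=None, **kwargs):
        """Draw the dendrogram with matplotlib (lazy import)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        hierarchy.dendrogram(self.merges, labels=self.labels, ax=ax, **kwargs)
        return ax


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA clustering of a symmetric distance matrix.

    Inter-cluster distance is the arithmetic mean of pairwise member
    distances; scipy's deterministic merge order breaks ties by index.
    """
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = squareform(arr, checks=False)
    merges = hierarchy.linkage(condensed, method="average")
    return Dendrogram(merges=merges, labels=list(map(str, dist.index)))


def cluster_matrix(matrix: ExpressionMatrix | pd.DataFrame,
                   axis: str = "features") -> Dendrogram:
    """Convenience: Pearson distance followed by average linkage."""
    return average_linkage(pearson_distance(matrix, axis=axis))
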