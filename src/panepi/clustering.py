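"""Hierarchical clustering of epigenome matrices and dendrogram comparison.

Profiles (methylation-frequency or presence/absence matrices) are clustered
by complete-linkage agglomeration on Euclidean distances — the standard
`hclust(d, method = "complete")` recipe. Two dendrograms over the same
strain set are compared through the Pearson correlation of their cophenetic
distance matrices; a precomputed phylogeny read from Newick can stand in
for either side via its patristic distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps
import skbio

__all__ = [
    "Dendrogram",
    "euclidean_distance_matrix",
    "hcluster_complete",
    "cophenetic_distances",
    "cophenetic_correlation",
    "presence_absence_cluster",
    "read_newick_distances",
]


@dataclass
class Dendrogram:
    """A complete-linkage merge tree over labeled leaves.

    ``linkage`` is the standard (n-1, 4) agglomeration matrix; ``labels``
    are sorted lexicographically before clustering so that tie-breaking in
    the agglomeration is deterministic and independent of input order.
    """

    labels: list[str]
    linkage: np.ndarray
    method: str = "complete"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Newick text with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.12g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.12g}"

        root = tree
        inner = (f"({render(root.left, root.dist)},"
                 f"{render(root.right, root.dist)})")
        return inner + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def euclidean_distance_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between the rows of ``m``."""
    if m.shape[0] < 2:
        raise ValueError("need at least 2 entities to compute distances")
    if m.isna().any().any():
        raise ValueError("distance matrix input contains missing values; "
                         "impute upstream")
    d = squareform(pdist(m.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=m.index, columns=m.index)


def hcluster_complete(d: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration of a labeled distance matrix.

    Leaves are ordered lexicographically first, which fixes the merge
    order among exactly tied candidate pairs.
    """
    labels = sorted(str(x) for x in d.index)
    if list(d.index) != list(d.columns):
        raise ValueError("distance matrix rows and columns must agree")
    d = d.loc[labels, labels]
    condensed = squareform(d.to_numpy(dtype=float), checks=True)
    Z = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(labels=labels, linkage=Z)


def cophenetic_distances(t: Dendrogram) -> pd.DataFrame:
    """Cophenetic matrix: entry (i, j) is the merge height at which leaves
    i and j first join. Symmetric, zero diagonal, ultrametric."""
    if t.n_leaves < 2:
        raise ValueError("cophenetic distances need >= 2 leaves")
    coph = squareform(hierarchy.cophenet(t.linkage))
    return pd.DataFrame(coph, index=t.labels, columns=t.labels)


def _as_cophenetic(x: "Dendrogram | pd.DataFrame") -> pd.DataFrame:
    return cophenetic_distances(x) if isinstance(x, Dendrogram) else x


def cophenetic_correlation(t1: "Dendrogram | pd.DataFrame",
                           t2: "Dendrogram | pd.DataFrame",
                           method: Literal["pearson", "spearman"] = "pearson",
                           ) -> float:
    """Correlation between the cophenetic structures of two trees.

    Arguments are dendrograms or precomputed leaf-distance matrices (e.g.
    patristic distances of an external phylogeny). Leaves are aligned by
    label; the upper triangles of both matrices are vectorized and
    correlated (Pearson by default).
    """
    m1, m2 = _as_cophenetic(t1), _as_cophenetic(t2)
    s1, s2 = set(m1.index), set(m2.index)
    if s1 != s2:
        raise ValueError("leaf sets differ; symmetric difference: "
                         f"{sorted(s1 ^ s2)}")
    labels = sorted(s1)
    a = m1.loc[labels, labels].to_numpy(dtype=float)
    b = m2.loc[labels, labels].to_numpy(dtype=float)
    iu = np.triu_indices(len(labels), k=1)
    va, vb = a[iu], b[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        warnings.warn("zero variance in a cophenetic vector; "
                      "correlation undefined")
        return float("nan")
    if method == "spearman":
        return float(sps.spearmanr(va, vb).statistic)
    return float(np.corrcoef(va, vb)[0, 1])


def presence_absence_cluster(matrix: pd.DataFrame) -> Dendrogram:
    """Cluster strains from a gene x strain presence/absence matrix.

    Strains (columns) are embedded as 0/1 vectors; two strains differing
    in k genes sit at Euclidean distance sqrt(k). Reuses the Euclidean +
    complete-linkage pipeline.
    """
    binary = matrix.astype(float).T  # strains x genes
    return hcluster_complete(euclidean_distance_matrix(binary))


def read_newick_distances(path: str | Path) -> pd.DataFrame:
    """Patristic tip-to-tip distance matrix of a Newick phylogeny.

    Feeds :func:`cophenetic_correlation` directly, standing in for a
    dendrogram when the tree was built elsewhere.
    """
    tree = skbio.TreeNode.read(str(path))
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
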