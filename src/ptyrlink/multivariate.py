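"""Exploratory multivariate structure: PCA, Pearson-distance clustering,
and correlation maps.

PCA is computed by singular value decomposition of the (column-centered,
optionally unit-variance-scaled) data matrix.  Hierarchical clustering uses
the Pearson correlation distance d = 1 - r by default, matching standard
practice for signaling trajectory data where shape, not magnitude, defines
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .types import PtyrlinkError


class ZeroVarianceError(PtyrlinkError):
    """A vector with zero variance cannot enter a correlation."""


@dataclass
class PcaResult:
    scores: pd.DataFrame  # observation x component
    loadings: pd.DataFrame  # feature x component (orthonormal columns)
    variance_explained_pct: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> PcaResult:
    """SVD-based principal component analysis of observations x features.

    At full rank, ``scores @ loadings.T`` reconstructs the processed matrix.
    """
    if matrix.isna().any().any():
        raise PtyrlinkError(
            "PCA input has missing cells; apply presence_filter / feature "
            "completion first"
        )
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 observations")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if not (sd > 0).all():
            bad = matrix.columns[~(sd > 0)][0]
            raise ZeroVarianceError(f"feature {bad!r} has zero variance")
        X = X / sd
    rank_cap = min(n - (1 if center else 0), p)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(rank_cap, len(s))
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=matrix.index, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=matrix.columns, columns=comps)
    var = s[:k] ** 2
    total = (s**2).sum()
    pct = pd.Series(100.0 * var / total if total > 0 else np.zeros(k), index=comps)
    return PcaResult(scores=scores, loadings=loadings, variance_explained_pct=pct)


def pearson_distance(matrix: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Pairwise Pearson correlation distance, d = 1 - r, in [0, 2]."""
    if axis == "rows":
        data = matrix
    elif axis == "columns":
        data = matrix.T
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    arr = data.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise PtyrlinkError("pearson_distance input has missing cells")
    sd = arr.std(axis=1)
    if not (sd > 0).all():
        bad = data.index[~(sd > 0)][0]
        raise ZeroVarianceError(f"vector {bad!r} has zero variance")
    r = np.corrcoef(arr)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=data.index, columns=data.index)


@dataclass
class LinkageTree:
    """Agglomerative merge history with labeled leaves."""

    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    labels: list[str]

    def cut(
        self, n_clusters: int | None = None, height: float | None = None
    ) -> pd.Series:
        if (n_clusters is None) == (height is None):
            raise ValueError("specify exactly one of n_clusters or height")
        if n_clusters is not None:
            if not 1 <= n_clusters <= len(self.labels):
                raise ValueError(f"n_clusters must be in [1, {len(self.labels)}]")
            flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        else:
            flat = hierarchy.fcluster(self.linkage, height, criterion="distance")
        return pd.Series(flat, index=self.labels, name="cluster")

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


def hcluster(dist: pd.DataFrame, linkage: str = "average") -> LinkageTree:
    """Agglomerative clustering of a symmetric distance matrix."""
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise PtyrlinkError("hcluster requires a symmetric distance matrix")
    condensed = squareform(arr, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return LinkageTree(linkage=Z, labels=[str(x) for x in dist.index])


@dataclass
class CorrelationMap:
    r: pd.DataFrame
    tree: LinkageTree

    @property
    def order(self) -> list[str]:
        return self.tree.leaf_order()

    def reordered(self) -> pd.DataFrame:
        order = self.order
        return self.r.loc[order, order]

    def subcluster(self, n_clusters: int) -> pd.Series:
        return self.tree.cut(n_clusters=n_clusters)


def correlation_map(
    matrix: pd.DataFrame, axis: str = "rows", linkage: str = "average"
) -> CorrelationMap:
    """Symmetric Pearson r matrix with a clustered display ordering.

    Used both for cell-line similarity (lines x features input) and for
    peptide co-correlation maps (peptides x conditions input).
    """
    d = pearson_distance(matrix, axis=axis)
    tree = hcluster(d, linkage=linkage)
    arr = 1.0 - d.to_numpy()
    np.fill_diagonal(arr, 1.0)
    r = pd.DataFrame(arr, index=d.index, columns=d.columns)
    return CorrelationMap(r=r, tree=tree)
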