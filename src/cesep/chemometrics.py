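"""Chemophenetic classification of species metabolite profiles.

Species are compared by their metabolite concentration profiles (mg/g dry
weight) using

- semiquantitative content categories (absent / * <=2 / ** 2-10 / *** >10
  mg/g DW),
- hierarchical clustering on the Pearson correlation distance
  d(a, b) = 1 - r(a, b)  (note 1 - r is not a metric: the triangle
  inequality may fail; it is used descriptively, as is common in
  chemotaxonomy), and
- principal component analysis on column-standardized (or raw)
  concentrations with a deterministic sign convention.

Clustering can equally be run on raw concentrations, on the category codes
or on presence/absence indicators; all three are plain row matrices here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

from .errors import DomainError

#: Content-category cut points in mg/g dry weight.
CATEGORY_BOUNDS = (2.0, 10.0)
CATEGORY_LABELS = ("absent", "*", "**", "***")


def quantity_category(x: float) -> str:
    """Semiquantitative content category for a concentration in mg/g DW."""
    if x < 0 or not np.isfinite(x):
        raise DomainError(f"concentration must be nonnegative and finite, got {x}")
    if x == 0:
        return "absent"
    if x <= CATEGORY_BOUNDS[0]:
        return "*"
    if x <= CATEGORY_BOUNDS[1]:
        return "**"
    return "***"


def categorize(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise content categories of a species x compound matrix."""
    return m.map(quantity_category)


def _rows(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), [str(i) for i in m.index]
    arr = np.atleast_2d(np.asarray(m, dtype=float))
    return arr, [f"row{i}" for i in range(arr.shape[0])]


def pearson_distance(m) -> np.ndarray:
    """Pairwise Pearson correlation distance 1 - r between profile rows."""
    arr, labels = _rows(m)
    if arr.shape[0] < 2:
        raise DomainError("need at least two profiles")
    sd = arr.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.where(sd == 0)[0]]
        raise DomainError(f"zero-variance profile(s): {bad}")
    r = np.corrcoef(arr)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class ClusterTree:
    """Agglomerative merge tree over profiles."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> tuple[str, ...]:
        order = _hier.leaves_list(self.linkage)
        return tuple(self.labels[i] for i in order)

    def cut(self, k: int) -> dict[str, int]:
        """Assign each profile to one of ``k`` groups."""
        flat = _hier.fcluster(self.linkage, t=k, criterion="maxclust")
        return {lab: int(g) for lab, g in zip(self.labels, flat)}

    def to_newick(self) -> str:
        """Dendrogram in Newick format with merge heights as branch lengths."""
        tree = _hier.to_tree(self.linkage)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hcluster(d: np.ndarray, linkage: str = "average", labels: Sequence[str] | None = None) -> ClusterTree:
    """Hierarchical clustering of a square distance matrix (UPGMA default)."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DomainError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise DomainError("distance matrix must be symmetric")
    condensed = squareform(d, checks=False)
    Z = _hier.linkage(condensed, method=linkage)
    if labels is None:
        labels = [f"row{i}" for i in range(d.shape[0])]
    return ClusterTree(linkage=Z, labels=tuple(str(l) for l in labels))


def cluster_profiles(m, linkage: str = "average") -> ClusterTree:
    """Convenience: Pearson-distance UPGMA tree straight from a profile matrix."""
    arr, labels = _rows(m)
    return hcluster(pearson_distance(arr), linkage=linkage, labels=labels)


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_rows, n_components)
    loadings: np.ndarray  # (n_cols, n_components)
    explained: np.ndarray  # variance fractions, sum to 1
    standardized: bool

    def reconstruct(self) -> np.ndarray:
        """Scores x loadings'; equals the (standardized) input with all PCs."""
        return self.scores @ self.loadings.T


def pca(m, standardize: bool = True) -> PCAResult:
    """PCA of a species x compound matrix via SVD.

    With ``standardize`` (default) columns are z-scored, i.e. the analysis
    is of the correlation structure; otherwise the covariance structure of
    the centered data.  Component signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    arr, _ = _rows(m)
    n, q = arr.shape
    if n < 2 or q < 2:
        raise DomainError("PCA needs at least 2 rows and 2 columns")
    centered = arr - arr.mean(axis=0)
    if standardize:
        sd = arr.std(axis=0, ddof=1)
        if np.any(sd == 0):
            if isinstance(m, pd.DataFrame):
                bad = [str(c) for c, s in zip(m.columns, sd) if s == 0]
            else:
                bad = [f"col{i}" for i in np.where(sd == 0)[0]]
            raise DomainError(f"constant column(s) cannot be standardized: {bad}")
        centered = centered / sd
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise DomainError("matrix has no variance")
    # Deterministic sign: largest |loading| positive per component.
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    return PCAResult(
        scores=u * s,
        loadings=vt.T,
        explained=var / total,
        standardized=standardize,
    )
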