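"""Unsupervised structure: PCA and Euclidean hierarchical clustering.

PCA runs on the run x protein matrix after centering each protein (covariance
PCA, no per-protein rescaling).  Component signs are fixed by making each
component's largest-magnitude loading positive, so results are deterministic.

Hierarchical clustering is agglomerative with a Euclidean metric; the linkage
method defaults to average (UPGMA).  Trees can be cut into k flat clusters and
exported as Newick text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .preprocess import LogMatrix

__all__ = [
    "PCAResult",
    "ClusterTree",
    "pca",
    "hierarchical_cluster",
    "cut_tree",
    "to_newick",
]

_LINKAGES = ("average", "complete", "single", "ward")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # runs x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_fraction: np.ndarray


@dataclass
class ClusterTree:
    """Agglomerative merge tree (scipy linkage encoding) over named leaves."""

    linkage: np.ndarray  # (n-1) x 4 scipy linkage matrix
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.leaves[i] for i in hierarchy.leaves_list(self.linkage)]


def pca(matrix: LogMatrix, n_components: int) -> PCAResult:
    """Principal components of runs in protein space (proteins centered)."""
    if not matrix.is_complete:
        raise ValueError("PCA requires a complete (imputed) matrix")
    X = matrix.values.to_numpy(dtype=float).T  # runs x proteins
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(runs, proteins)={min(X.shape)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # proteins x components

    # deterministic orientation: largest-|loading| entry positive per component
    for j in range(n_components):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.run_ids, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.protein_ids, columns=comp_names),
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
    )


def hierarchical_cluster(
    matrix: Union[LogMatrix, pd.DataFrame],
    axis: str = "runs",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of runs or proteins under Euclidean distance."""
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    values = matrix.values if isinstance(matrix, LogMatrix) else matrix
    if isinstance(matrix, LogMatrix) and not matrix.is_complete:
        raise ValueError("clustering requires a complete matrix")
    if axis == "runs":
        X = values.to_numpy(dtype=float).T
        labels = list(values.columns)
    elif axis == "proteins":
        X = values.to_numpy(dtype=float)
        labels = list(values.index)
    else:
        raise ValueError("axis must be 'runs' or 'proteins'")
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage)
    return ClusterTree(linkage=Z, leaves=labels)


def cut_tree(tree: ClusterTree, k: int) -> pd.Series:
    """Cut the merge tree into k flat clusters; labels indexed by leaf name."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in 1..{tree.n_leaves}")
    labels = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=tree.leaves, name="cluster")


def _newick(node, leaves: list[str]) -> str:
    if node.is_leaf():
        return leaves[node.id].replace(" ", "_")
    left = _newick(node.left, leaves)
    right = _newick(node.right, leaves)
    bl_left = node.dist - node.left.dist
    bl_right = node.dist - node.right.dist
    return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"


def to_newick(tree: ClusterTree) -> str:
    """Serialize the merge tree to Newick (branch lengths from merge heights)."""
    root = hierarchy.to_tree(tree.linkage)
    return _newick(root, tree.leaves) + ";"
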