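"""Community typing: Bray-Curtis distances, complete-linkage trees, PCoA.

Samples are grouped into community types by complete-linkage agglomeration
of Bray-Curtis dissimilarities, cut at a fixed height (0.8 in the reference
workflow).  The number of clusters is independently assessed with the
Calinski-Harabasz index — computed on principal-coordinate embeddings of
the distance matrix, since CH needs coordinates — and validated by the mean
silhouette width, which works on the distances directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .composition import CompositionTable
from .tableio import CountTableError

__all__ = [
    "DistanceMatrix",
    "ClusterModel",
    "PCoAResult",
    "bray_curtis",
    "hierarchical_cluster",
    "cut_into_k",
    "select_k",
    "pcoa",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal dissimilarities over samples."""

    values: pd.DataFrame
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        a = self.values.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1]:
            raise CountTableError("distance matrix must be square")
        if not np.allclose(a, a.T, atol=1e-9):
            raise CountTableError("distance matrix must be symmetric")
        if not np.allclose(np.diag(a), 0.0, atol=1e-9):
            raise CountTableError("distance matrix diagonal must be zero")
        if a.size and a.min() < -1e-12:
            raise CountTableError("negative dissimilarity")

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(dtype=float), checks=False)

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        return DistanceMatrix(self.values.loc[ids, ids], self.metric)


def bray_curtis(comp: CompositionTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample compositions.

    d_jk = sum_i |p_ij - p_ik| / sum_i (p_ij + p_ik); bounded [0, 1] on
    non-negative data, 0 for identical columns, 1 for disjoint support.
    """
    mat = comp.proportions.to_numpy(dtype=float).T  # samples x features
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(
        pd.DataFrame(d, index=comp.sample_ids, columns=comp.sample_ids),
        "braycurtis",
    )


@dataclass
class ClusterModel:
    """A complete-linkage dendrogram with a fixed-height cut.

    ``labels`` come from cutting every merge above ``cut_height``; clusters
    smaller than ``min_size`` are set aside (label ``0``, reported in
    ``small_clusters``) and excluded from downstream group comparisons,
    mirroring the exclusion of minor community types.
    """

    linkage: np.ndarray
    ids: list[str]
    cut_height: float
    labels: pd.Series
    min_size: int
    small_clusters: dict[int, list[str]] = field(default_factory=dict)
    scores: pd.DataFrame | None = None
    selected_k: int | None = None

    def retained_samples(self) -> list[str]:
        return [s for s in self.ids if self.labels[s] != 0]


def hierarchical_cluster(
    d: DistanceMatrix, cut_height: float = 0.8, min_size: int = 5
) -> ClusterModel:
    """Complete-linkage agglomeration of ``d``, cut at ``cut_height``.

    Complete linkage merges the two clusters whose *maximum* pairwise
    dissimilarity is smallest, giving monotone non-decreasing merge
    heights.  Clusters with fewer than ``min_size`` members after the cut
    are relabelled 0 and listed in ``small_clusters``; surviving clusters
    are renumbered 1..k by decreasing size.
    """
    if d.n < 2:
        raise CountTableError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(d.condensed(), method="complete")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=d.ids)
    sizes = labels.value_counts()
    big = sizes[sizes >= min_size].index
    # renumber surviving clusters by decreasing size (ties: first appearance)
    order = sorted(big, key=lambda c: (-sizes[c], list(labels).index(c)))
    remap = {c: i + 1 for i, c in enumerate(order)}
    small = {int(c): list(labels.index[labels == c])
             for c in sizes.index if c not in big}
    final = labels.map(lambda c: remap.get(c, 0))
    return ClusterModel(Z, d.ids, cut_height, final, min_size, small)


def cut_into_k(model: ClusterModel, k: int) -> pd.Series:
    """Labels from cutting the dendrogram into exactly ``k`` clusters."""
    raw = hierarchy.fcluster(model.linkage, t=k, criterion="maxclust")
    return pd.Series(raw, index=model.ids)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame     # samples x axes, eigenvalue order
    eigenvalues: np.ndarray       # positive eigenvalues backing the axes
    negative_eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Principal coordinate analysis (classical MDS) of a dissimilarity matrix.

    Gower-centers -d^2/2, eigendecomposes, and returns coordinates
    (eigenvectors scaled by sqrt eigenvalue) on the positive-eigenvalue
    axes in decreasing order.  Bray-Curtis is not Euclidean, so negative
    eigenvalues can occur; they are reported and their axes dropped.
    Proportions explained are relative to the positive eigenvalue total.
    """
    if n_axes is not None and n_axes < 1:
        raise CountTableError("n_axes must be >= 1")
    a = d.values.to_numpy(dtype=float)
    n = a.shape[0]
    b = -0.5 * a**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    g = centerer @ b @ centerer
    vals, vecs = eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, 1e-10 * abs(vals).max()) if n else 0.0
    pos = vals > tol
    neg = vals[vals < -tol]
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    pos_vals = vals[pos][: coords.shape[1]]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=d.ids, columns=axes),
        eigenvalues=pos_vals,
        negative_eigenvalues=neg,
        proportion_explained=pos_vals / vals[pos].sum() if pos.any() else pos_vals,
    )


def select_k(
    d: DistanceMatrix,
    model: ClusterModel,
    k_range: range | list[int] = range(2, 11),
) -> ClusterModel:
    """Score tree cuts at each k with Calinski-Harabasz and silhouette.

    CH(k) = [B/(k-1)] / [W/(n-k)] is computed on the full
    positive-eigenvalue PCoA embedding of ``d`` (CH needs coordinates; the
    embedding preserves the distance structure).  Mean silhouette width is
    computed directly on ``d``.  ``selected_k`` maximizes CH, ties broken
    toward smaller k.  Degenerate cuts (a k the tree cannot produce, or
    all points identical) get NaN scores.
    """
    n = d.n
    ks = [k for k in k_range]
    if any(k < 2 or k > n - 1 for k in ks):
        raise CountTableError(f"k_range must lie within [2, {n - 1}]")
    emb = pcoa(d).coordinates.to_numpy()
    dmat = d.values.to_numpy(dtype=float)
    rows = []
    for k in ks:
        lab = cut_into_k(model, k).to_numpy()
        ch = sil = np.nan
        if len(np.unique(lab)) == k and emb.shape[1] > 0:
            ch = calinski_harabasz_score(emb, lab)
            sil = silhouette_score(dmat, lab, metric="precomputed")
        rows.append({"k": k, "calinski_harabasz": ch, "silhouette": sil})
    scores = pd.DataFrame(rows).set_index("k")
    ch_col = scores["calinski_harabasz"]
    selected = int(ch_col.idxmax()) if ch_col.notna().any() else None
    model.scores = scores
    model.selected_k = selected
    return model


def to_newick(model: ClusterModel) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    tree = hierarchy.to_tree(model.linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{model.ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
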