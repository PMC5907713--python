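"""Agglomerative (Ward) clustering with variance-ratio cluster-number choice.

Dissimilarity is Euclidean distance on the standardized feature vectors;
linkage follows Ward's minimum-variance method; the number of clusters is
the maximizer of the Calinski-Harabasz variance-ratio criterion over a
scanned range.  A reference-null check (uniform samples on the data's PCA
bounding box) flags datasets with no detectable sub-structure — an
operationalization of "no sub-groups identified", added by this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class MergeTree:
    """Ward merge sequence; heights are within-cluster SSE increases."""

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]
    scipy_linkage: np.ndarray

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaf_ids) - 1:
            raise ValueError("a tree over n leaves must contain n - 1 merges")

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (1..k) from cutting the tree at k clusters."""
        n = len(self.leaf_ids)
        if not 1 <= k <= n:
            raise ValueError(f"k must lie in [1, {n}]")
        return fcluster(self.scipy_linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with SSE-increase branch heights."""
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}
        text = {i: self.leaf_ids[i] for i in range(n)}
        for idx, (a, b, h, _) in enumerate(self.merges):
            node = n + idx
            text[node] = (
                f"({text[a]}:{h - height[a]:.6g},{text[b]}:{h - height[b]:.6g})"
            )
            height[node] = h
        return text[2 * n - 2] + ";"


@dataclass
class ClusterSolution:
    """Selected partition plus the criterion profile and merge tree."""

    labels: dict
    k_selected: int
    vrc_by_k: dict
    tree: MergeTree
    no_substructure: bool = False
    null_vrc_quantile: float | None = None

    def labels_array(self, subject_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in subject_ids])


def distance_matrix(X: np.ndarray) -> np.ndarray:
    """Symmetric pairwise Euclidean distances with zero diagonal."""
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("non-finite rows in feature matrix")
    return squareform(pdist(X, metric="euclidean"))


def ward_linkage(X: np.ndarray, leaf_ids: list[str] | None = None) -> MergeTree:
    """Ward's minimum-variance agglomeration of the rows of X.

    Each merge joins the pair whose union minimally increases total
    within-cluster sum of squares; recorded heights are those SSE increases
    (scipy's cophenetic distance d relates as delta_SSE = d^2 / 2).
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    Z = linkage(X, method="ward")
    merges = [
        (int(a), int(b), float(d**2 / 2.0), int(size)) for a, b, d, size in Z
    ]
    return MergeTree(merges=merges, leaf_ids=list(leaf_ids), scipy_linkage=Z)


def variance_ratio(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz criterion:
    [tr(B)/(k-1)] / [tr(W)/(n-k)] for k clusters over n points.

    Returns +inf (perfect separation) when all within-cluster variance is 0.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = X.shape[0]
    groups = np.unique(labels)
    k = len(groups)
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    grand = X.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for g in groups:
        rows = X[labels == g]
        if rows.shape[0] == 0:
            raise ValueError(f"empty cluster {g!r}")
        c = rows.mean(axis=0)
        tr_b += rows.shape[0] * float(np.sum((c - grand) ** 2))
        tr_w += float(np.sum((rows - c) ** 2))
    if tr_w == 0.0:
        return float("inf")
    return (tr_b / (k - 1)) / (tr_w / (n - k))


def _null_vrc_max(
    X: np.ndarray, k_range: range, rng: np.random.Generator
) -> float:
    """Best criterion value on one reference-null dataset: points drawn
    uniformly on the data's bounding box in its own principal axes."""
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    proj = Xc @ Vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    null = rng.uniform(lo, hi, size=proj.shape)
    tree = ward_linkage(null)
    best = -np.inf
    for k in k_range:
        if k >= null.shape[0]:
            break
        v = variance_ratio(null, tree.cut(k))
        best = max(best, v)
    return best


def select_k(
    X: np.ndarray,
    tree: MergeTree,
    k_range: range | None = None,
    n_null: int = 99,
    null_quantile: float = 0.95,
    rng: np.random.Generator | None = None,
) -> ClusterSolution:
    """Scan k over ``k_range``, score each cut with the variance-ratio
    criterion and select the maximizer (ties broken toward smaller k).

    When ``n_null > 0``, the observed best criterion value is compared with
    the ``null_quantile`` quantile of best values over reference-null
    datasets; failing that check raises the ``no_substructure`` flag.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range contains no feasible k")
    vrc_by_k = {k: variance_ratio(X, tree.cut(k)) for k in ks}
    best = max(vrc_by_k.values())
    k_selected = min(k for k, v in vrc_by_k.items() if v == best)
    labels_arr = tree.cut(k_selected)
    labels = {sid: int(lab) for sid, lab in zip(tree.leaf_ids, labels_arr)}

    no_structure = False
    null_q = None
    if n_null > 0:
        rng = rng or np.random.default_rng(0)
        maxima = [_null_vrc_max(X, range(ks[0], ks[-1] + 1), rng) for _ in range(n_null)]
        null_q = float(np.quantile(maxima, null_quantile))
        no_structure = bool(best <= null_q)

    return ClusterSolution(
        labels=labels,
        k_selected=int(k_selected),
        vrc_by_k=vrc_by_k,
        tree=tree,
        no_substructure=no_structure,
        null_vrc_quantile=null_q,
    )
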