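"""Expression-profile clustering: DIANA divisive hierarchy, profile
matrices, and PCA summaries.

Differentially expressed genes are summarized as z-scored per-(group,
stage) mean profiles and clustered top-down with DIANA (DIvisive ANAlysis,
Kaufman & Rousseeuw): starting from one all-object cluster, repeatedly
split the cluster of largest diameter by seeding a splinter group with the
most-average-dissimilar object and reallocating objects toward the splinter
while that strictly reduces their average dissimilarity.  Split height is
the parent diameter, so heights decrease from root to leaves and the split
sequence doubles as a dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .normalization import normalized_counts

__all__ = [
    "ProfileMatrix",
    "profile_matrix",
    "DianaTree",
    "diana_tree",
    "cut_tree",
    "correlation_dissimilarity",
    "pca_summary",
    "DianaClustering",
]


# ---------------------------------------------------------------------------
# profile construction


@dataclass
class ProfileMatrix:
    """Gene-by-(group, stage) matrix of z-scored mean expression profiles."""

    gene_ids: pd.Index
    cell_labels: list[tuple[str, str]]  # (group, stage_label) in time order
    values: np.ndarray
    constant: np.ndarray  # flag: gene had a constant profile (row left all-zero)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{g}|{s}" for g, s in self.cell_labels]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


def profile_matrix(
    counts: np.ndarray,
    sf: np.ndarray,
    metadata: pd.DataFrame,
    grouping: str = "fruit_type",
    gene_ids=None,
) -> ProfileMatrix:
    """Per-gene z-scored profiles of mean normalized expression.

    For each (group, stage) cell: average ``count / size_factor`` over the
    cell's replicates, transform ``log2(x + 1)``, then z-score each gene
    across cells using the sample standard deviation (ddof=1).  Genes with
    a constant profile get an all-zero row and are flagged.
    """
    if grouping not in ("species", "fruit_type"):
        raise ValueError("grouping must be 'species' or 'fruit_type'")
    counts = np.asarray(counts)
    if gene_ids is None:
        gene_ids = pd.RangeIndex(counts.shape[0])
    norm = normalized_counts(counts, sf)
    cells = (
        metadata[[grouping, "stage_label", "time"]]
        .drop_duplicates()
        .sort_values([grouping, "time"], kind="mergesort")
    )
    labels: list[tuple[str, str]] = []
    means = []
    for _, row in cells.iterrows():
        mask = (
            (metadata[grouping] == row[grouping])
            & (metadata["stage_label"] == row["stage_label"])
        ).to_numpy()
        if not mask.any():
            raise ValueError(f"empty cell: ({row[grouping]}, {row['stage_label']})")
        labels.append((str(row[grouping]), str(row["stage_label"])))
        means.append(norm[:, mask].mean(axis=1))
    M = np.log2(np.column_stack(means) + 1.0)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[constant] = 1.0
    Z = (M - mu) / sd
    Z[constant] = 0.0
    return ProfileMatrix(pd.Index(gene_ids), labels, Z, constant)


def correlation_dissimilarity(values: np.ndarray) -> np.ndarray:
    """(1 - Pearson correlation) / 2 between profile rows, in [0, 1]."""
    v = np.asarray(values, dtype=float)
    sd = v.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant rows have undefined correlation; drop them first")
    corr = np.corrcoef(v)
    d = (1.0 - corr) / 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


# ---------------------------------------------------------------------------
# DIANA


@dataclass
class Split:
    members: tuple[int, ...]
    left: tuple[int, ...]
    right: tuple[int, ...]
    height: float


@dataclass
class DianaTree:
    """Ordered record of divisive splits; heights are parent diameters."""

    n: int
    splits: list[Split] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "order": i,
                "height": s.height,
                "members": list(s.members),
                "left": list(s.left),
                "right": list(s.right),
            }
            for i, s in enumerate(self.splits)
        ]


def _check_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(d < 0):
        raise ValueError("dissimilarity must be non-negative")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("dissimilarity must have a zero diagonal")
    return d


def _split_cluster(d: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One DIANA split: seed the splinter, then reallocate.

    Seed = object with maximal average dissimilarity to the others; an
    object moves when (avg dissimilarity to its own side minus avg to the
    splinter) is maximal and strictly positive.  Ties break on the lowest
    object index.
    """
    idx = np.array(members)
    sub = d[np.ix_(idx, idx)]
    m = len(members)
    avg = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmax(avg))  # argmax takes the first (lowest index) on ties
    in_b = np.zeros(m, dtype=bool)
    in_b[seed] = True
    while (~in_b).sum() > 1:
        a_idx = np.nonzero(~in_b)[0]
        na = len(a_idx)
        nb = int(in_b.sum())
        d_a = sub[np.ix_(a_idx, a_idx)].sum(axis=1) / (na - 1)
        d_b = sub[np.ix_(a_idx, in_b.nonzero()[0])].sum(axis=1) / nb
        diff = d_a - d_b
        j = int(np.argmax(diff))
        if diff[j] > 0:
            in_b[a_idx[j]] = True
        else:
            break
    left = [members[i] for i in range(m) if not in_b[i]]
    right = [members[i] for i in range(m) if in_b[i]]
    return left, right


def diana_tree(dissimilarity: np.ndarray) -> DianaTree:
    """Full divisive hierarchy of the objects of a dissimilarity matrix.

    Always splits the cluster of current largest diameter (ties: lowest
    member index); records splits until every cluster is a singleton, so a
    matrix of ``n`` objects yields ``n - 1`` splits with non-increasing
    heights along every root-to-leaf path.
    """
    d = _check_dissimilarity(dissimilarity)
    n = d.shape[0]
    tree = DianaTree(n=n)
    if n <= 1:
        return tree
    clusters: list[list[int]] = [list(range(n))]
    while clusters:
        diam = []
        for c in clusters:
            sub = d[np.ix_(c, c)]
            diam.append(sub.max() if len(c) > 1 else 0.0)
        # largest diameter; ties by lowest member index
        order = sorted(range(len(clusters)), key=lambda i: (-diam[i], clusters[i][0]))
        ci = order[0]
        c = clusters.pop(ci)
        height = diam[ci]
        left, right = _split_cluster(d, c)
        tree.splits.append(Split(tuple(c), tuple(left), tuple(right), float(height)))
        for child in (left, right):
            if len(child) > 1:
                clusters.append(child)
    tree.splits.sort(key=lambda s: (-s.height, s.members[0]))
    return tree


def cut_tree(
    tree: DianaTree,
    k: int | None = None,
    height: float | None = None,
    min_size: int = 15,
) -> pd.Series:
    """Cut the divisive tree into flat clusters.

    Either the first ``k - 1`` splits are applied, or every split with
    height strictly above ``height``.  Clusters smaller than ``min_size``
    are unassigned (label 0); assigned labels are contiguous from 1, in
    order of each cluster's smallest member index.
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    n = tree.n
    if k is not None:
        if not (1 <= k <= n):
            raise ValueError(f"k={k} out of range [1, {n}]")
        applied = tree.splits[: k - 1]
    else:
        if height < 0:
            raise ValueError("height must be >= 0")
        applied = [s for s in tree.splits if s.height > height]
    clusters: list[set] = [set(range(n))]
    for s in applied:
        mem = set(s.members)
        for i, c in enumerate(clusters):
            if c == mem:
                clusters[i] = set(s.left)
                clusters.append(set(s.right))
                break
        else:  # split refers to a cluster not currently present (shouldn't happen)
            raise RuntimeError("inconsistent split sequence")
    clusters.sort(key=min)
    labels = np.zeros(n, dtype=int)
    next_label = 1
    for c in clusters:
        if len(c) >= min_size:
            labels[sorted(c)] = next_label
            next_label += 1
    return pd.Series(labels, name="cluster")


# ---------------------------------------------------------------------------
# PCA


def pca_summary(values: np.ndarray, n_components: int | None = None) -> dict:
    """Centered-SVD principal components of a rows-as-observations matrix.

    Returns ``{"scores", "components", "percent_variance"}``; percent
    variance is non-increasing and sums to at most 100.  A constant matrix
    yields all-zero variance explained, flagged via ``"degenerate": True``.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("need a matrix with at least 2 rows and 2 columns")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    if total <= 0:
        k = n_components or min(X.shape)
        return {
            "scores": np.zeros((X.shape[0], k)),
            "components": Vt[:k],
            "percent_variance": np.zeros(k),
            "degenerate": True,
        }
    if n_components is not None:
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    return {
        "scores": U * s,
        "components": Vt,
        "percent_variance": 100.0 * (s**2) / total,
        "degenerate": False,
    }


# ---------------------------------------------------------------------------
# sklearn-style front end


class DianaClustering(ClusterMixin, BaseEstimator):
    """DIANA divisive clustering with a scikit-learn estimator surface.

    Parameters
    ----------
    k : int or None
        Number of clusters to cut; mutually exclusive with ``height``.
    height : float or None
        Cut height (splits with height strictly above it are applied).
        When both ``k`` and ``height`` are None, ``k=2`` is used.
    min_size : int
        Clusters smaller than this are left unassigned (label 0).
    metric : {'correlation', 'euclidean', 'precomputed'}
        Dissimilarity between profile rows; ``correlation`` is
        ``(1 - Pearson r) / 2``.

    Attributes
    ----------
    tree_ : DianaTree
        The full divisive hierarchy.
    labels_ : ndarray of int
        Flat cluster labels (1-based; 0 = unassigned).
    dissimilarity_ : ndarray
        The dissimilarity matrix that was clustered.
    """

    def __init__(self, k=None, height=None, min_size=1, metric="correlation"):
        self.k = k
        self.height = height
        self.min_size = min_size
        self.metric = metric

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.metric == "precomputed":
            d = X
        elif self.metric == "euclidean":
            from scipy.spatial.distance import pdist, squareform

            d = squareform(pdist(X))
        elif self.metric == "correlation":
            d = correlation_dissimilarity(X)
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        self.dissimilarity_ = _check_dissimilarity(d)
        self.tree_ = diana_tree(self.dissimilarity_)
        k, height = self.k, self.height
        if k is None and height is None:
            k = 2
        self.labels_ = cut_tree(
            self.tree_, k=k, height=height, min_size=self.min_size
        ).to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
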