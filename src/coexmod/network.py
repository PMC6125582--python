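"""Co-expression network construction and module detection.

An unsigned weighted adjacency (absolute Pearson correlation) is
hard-thresholded at tau, turned into a topological-overlap dissimilarity,
clustered with average linkage, and cut with a shape-based dynamic tree
cut. ``tune_hard_threshold`` repeats the chain over a grid of tau values
and keeps the one whose mean module size is closest to a target, so the
resulting modules have comparable sizes for downstream set scoring.

TOM similarity for i != j:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with ``l_ij = sum_u a_iu a_uj`` (shared-neighbor strength) and
``k_i = sum_u a_iu`` (connectivity); the dissimilarity is ``1 - TOM``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "correlation_adjacency",
    "hard_threshold",
    "tom_dissimilarity",
    "average_linkage",
    "dynamic_tree_cut",
    "tune_hard_threshold",
    "CoexpressionModuleDetector",
]


def correlation_adjacency(expr: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Unsigned adjacency: |Pearson r| between genes, zero diagonal."""
    X = expr.to_numpy(dtype=float) if isinstance(expr, pd.DataFrame) else np.asarray(expr, float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        names = (
            [str(expr.columns[i]) for i in bad[:5]]
            if isinstance(expr, pd.DataFrame)
            else list(bad[:5])
        )
        raise ValueError(f"zero-variance genes: {names}")
    adj = np.abs(np.corrcoef(X, rowvar=False))
    np.clip(adj, 0.0, 1.0, out=adj)
    np.fill_diagonal(adj, 0.0)
    return adj


def hard_threshold(adj: np.ndarray, tau: float, binarize: bool = False) -> np.ndarray:
    """Zero out entries below tau; above-threshold entries keep their
    weight (or become 1 when ``binarize``)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    out = np.where(adj >= tau, adj, 0.0) if not binarize else (adj >= tau).astype(float)
    if binarize:
        np.fill_diagonal(out, 0.0)
    return out


def tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity ``1 - TOM`` of a weighted adjacency.

    Degenerate denominators (an isolated pair with a_ij = 1) map to
    TOM = 0 — maximally dissimilar — with a warning.
    """
    A = np.asarray(adj, dtype=float)
    # zero diagonal makes A @ A exclude u = i and u = j automatically
    L = A @ A
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, (L + A) / denom, 0.0)
    if (denom <= 0).any():
        n_bad = int(np.sum(denom <= 0) - np.sum(np.diag(denom) <= 0))
        if n_bad > 0:
            warnings.warn(
                f"{n_bad} gene pairs had a non-positive TOM denominator; "
                "set to maximal dissimilarity",
                RuntimeWarning,
                stacklevel=2,
            )
    np.clip(tom, 0.0, 1.0, out=tom)
    np.fill_diagonal(tom, 1.0)
    d = 1.0 - tom
    return (d + d.T) / 2.0


def average_linkage(d: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerate a square dissimilarity matrix (UPGMA by default)."""
    condensed = squareform(np.asarray(d, dtype=float), checks=False)
    return linkage(condensed, method=method)


def _internal_heights(node) -> np.ndarray:
    """Merge heights strictly inside a branch (its own merge excluded)."""
    heights = []
    stack = [node.left, node.right]
    while stack:
        sub = stack.pop()
        if sub.is_leaf():
            continue
        heights.append(sub.dist)
        stack.append(sub.left)
        stack.append(sub.right)
    return np.asarray(heights)


def dynamic_tree_cut(
    Z: np.ndarray,
    d: np.ndarray,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
    split_gap: float = 0.15,
) -> np.ndarray:
    """Shape-based adaptive dendrogram cut into gene modules.

    Top-down over the tree: a branch splits into its children when its
    merge height exceeds the static cut height (``cut_height_quantile``
    times the maximum merge height, the usual static-cut convention) or
    when its merge
    height stands proud of the bulk of the merges inside it — the
    relative depth ``(h - median internal height) / h`` exceeds
    ``split_gap``. A large relative depth is the signature of separated
    sub-clusters, or of stray genes chained onto a branch near its top,
    which the recursion thereby peels off; the median is insensitive to
    those few high chain merges, while a tight homogeneous branch has
    its median hugging its merge height and is kept whole.
    Sub-threshold branches produced by splitting become candidates for
    re-merging: branches smaller than ``min_module_size`` are merged
    into the nearest accepted branch by average inter-branch
    dissimilarity, provided the join height stays below the cut height
    and would not itself trigger the split rule against the branch's
    top internal merge; otherwise they are labeled 0 (unassigned).
    Labels are renumbered by decreasing module size (1 = largest).
    """
    n = Z.shape[0] + 1
    if min_module_size > n:
        raise ValueError(f"min_module_size={min_module_size} exceeds {n} genes")
    heights = Z[:, 2]
    cut_height = float(cut_height_quantile * heights.max())
    root = to_tree(Z)

    clusters: list[list[int]] = []
    cluster_tops: list[float] = []
    pieces: list[list[int]] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf() or node.count < min_module_size:
            pieces.append(node.pre_order(lambda x: x.id))
            continue
        split = node.dist > cut_height
        if not split and node.dist > 0:
            inner = _internal_heights(node)
            if inner.size:
                depth = (node.dist - np.median(inner)) / node.dist
                split = depth >= split_gap
        if split:
            stack.append(node.left)
            stack.append(node.right)
        else:
            clusters.append(node.pre_order(lambda x: x.id))
            cluster_tops.append(node.dist)

    labels = np.zeros(n, dtype=int)
    for lab, leaves in enumerate(clusters, start=1):
        labels[leaves] = lab

    # fold small pieces into the nearest cluster, if near enough
    D = np.asarray(d, dtype=float)
    for leaves in pieces:
        if not clusters:
            break
        avg = [D[np.ix_(leaves, cl)].mean() for cl in clusters]
        best = int(np.argmin(avg))
        if avg[best] <= cut_height and avg[best] * (1.0 - split_gap) <= cluster_tops[best]:
            labels[leaves] = best + 1

    return _renumber_by_size(labels)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    nonzero = [lab for lab in np.unique(labels) if lab != 0]
    sizes = {lab: int(np.sum(labels == lab)) for lab in nonzero}
    first = {lab: int(np.argmax(labels == lab)) for lab in nonzero}
    order = sorted(nonzero, key=lambda lab: (-sizes[lab], first[lab]))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    return np.array([mapping[lab] for lab in labels], dtype=int)


def module_sizes(labels: np.ndarray) -> dict[int, int]:
    uniq, counts = np.unique(labels[labels != 0], return_counts=True)
    return {int(u): int(c) for u, c in zip(uniq, counts)}


@dataclass
class ThresholdReport:
    table: pd.DataFrame  # per tau: n_modules, size mean/min/max, n_unassigned
    tau: float


def tune_hard_threshold(
    expr: pd.DataFrame | np.ndarray,
    grid: list[float],
    target_mean_size: int = 200,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
    split_gap: float = 0.15,
    binarize: bool = False,
    adjacency: np.ndarray | None = None,
) -> tuple[float, np.ndarray, pd.DataFrame]:
    """Pick the hard threshold whose modules are closest to a target size.

    Runs threshold -> TOM -> linkage -> tree cut for each tau in the
    grid and selects the tau minimizing |mean nonzero-module size -
    target_mean_size|; ties break toward the smaller tau. Grid points
    yielding no modules are skipped with a warning. Returns
    ``(tau_star, labels, report)``.
    """
    grid = sorted(set(float(t) for t in grid))
    if not grid:
        raise ValueError("empty threshold grid")
    base = correlation_adjacency(expr) if adjacency is None else np.asarray(adjacency)
    rows = []
    best: tuple[float, float, np.ndarray] | None = None
    for tau in grid:
        A = hard_threshold(base, tau, binarize=binarize)
        D = tom_dissimilarity(A)
        Z = average_linkage(D)
        labels = dynamic_tree_cut(
            Z,
            D,
            min_module_size=min_module_size,
            cut_height_quantile=cut_height_quantile,
            split_gap=split_gap,
        )
        sizes = list(module_sizes(labels).values())
        if not sizes:
            warnings.warn(f"tau={tau} produced no modules; skipped", RuntimeWarning)
            rows.append(
                {"tau": tau, "n_modules": 0, "mean_size": np.nan, "min_size": np.nan,
                 "max_size": np.nan, "n_unassigned": int(np.sum(labels == 0))}
            )
            continue
        mean_size = float(np.mean(sizes))
        rows.append(
            {
                "tau": tau,
                "n_modules": len(sizes),
                "mean_size": mean_size,
                "min_size": int(min(sizes)),
                "max_size": int(max(sizes)),
                "n_unassigned": int(np.sum(labels == 0)),
            }
        )
        objective = abs(mean_size - target_mean_size)
        if best is None or objective < best[0]:
            best = (objective, tau, labels)
    if best is None:
        raise ValueError("every grid point produced zero modules")
    report = pd.DataFrame(rows)
    return best[1], best[2], report


class CoexpressionModuleDetector(BaseEstimator, ClusterMixin):
    """Cluster genes into co-expression modules via hard-thresholded TOM.

    Parameters
    ----------
    tau : float
        Hard threshold on |correlation| (used when ``tau_grid`` is None).
    tau_grid : sequence of float, optional
        When given, tau is tuned so the mean module size approaches
        ``target_mean_size``.
    target_mean_size, min_module_size : int
        Size target for tuning and the smallest admissible module.
    cut_height_quantile, split_gap : float
        Dynamic tree cut parameters (static cut quantile; relative
        height-drop needed to split a branch).
    binarize : bool
        Replace surviving edge weights with 1 (unweighted network).

    Attributes
    ----------
    labels_ : ndarray of int, 0 = unassigned
    tau_ : float, the threshold actually used
    adjacency_ : thresholded adjacency the modules were cut from
    gene_ids_ : gene identifiers in column order
    modules_ : dict label -> list of gene ids
    tuning_report_ : DataFrame (only when a grid was supplied)
    """

    def __init__(
        self,
        tau: float = 0.2,
        tau_grid=None,
        target_mean_size: int = 200,
        min_module_size: int = 30,
        cut_height_quantile: float = 0.99,
        split_gap: float = 0.15,
        binarize: bool = False,
    ):
        self.tau = tau
        self.tau_grid = tau_grid
        self.target_mean_size = target_mean_size
        self.min_module_size = min_module_size
        self.cut_height_quantile = cut_height_quantile
        self.split_gap = split_gap
        self.binarize = binarize

    def fit(self, X: pd.DataFrame, y=None):
        self.gene_ids_ = (
            list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.asarray(X).shape[1]))
        )
        base = correlation_adjacency(X)
        if self.tau_grid is not None:
            self.tau_, self.labels_, self.tuning_report_ = tune_hard_threshold(
                X,
                list(self.tau_grid),
                target_mean_size=self.target_mean_size,
                min_module_size=self.min_module_size,
                cut_height_quantile=self.cut_height_quantile,
                split_gap=self.split_gap,
                binarize=self.binarize,
                adjacency=base,
            )
        else:
            self.tau_ = float(self.tau)
            A = hard_threshold(base, self.tau_, binarize=self.binarize)
            D = tom_dissimilarity(A)
            Z = average_linkage(D)
            self.dendrogram_ = Z
            self.labels_ = dynamic_tree_cut(
                Z,
                D,
                min_module_size=self.min_module_size,
                cut_height_quantile=self.cut_height_quantile,
                split_gap=self.split_gap,
            )
        self.adjacency_ = hard_threshold(base, self.tau_, binarize=self.binarize)
        self.modules_ = {
            lab: [self.gene_ids_[i] for i in np.flatnonzero(self.labels_ == lab)]
            for lab in sorted(module_sizes(self.labels_))
        }
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_

    @property
    def gene_sets_(self) -> dict[str, list[str]]:
        return {f"M{lab}": genes for lab, genes in self.modules_.items()}

    @property
    def module_sizes_(self) -> dict[int, int]:
        return module_sizes(self.labels_)
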