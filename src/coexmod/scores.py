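"""Single-sample gene set enrichment (ssGSEA) module scores.

Each sample's expression vector is reduced to one score per gene module:
genes are ranked by expression (descending; ties broken by gene id for
reproducibility), ranks from the bottom are weighted by an exponent
``alpha``, and the score is the sum over the ranked list of the running
difference between the weighted empirical CDF of in-set genes and the
unweighted CDF of out-of-set genes:

    ES = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{j <= i, g_j in S} r_j^alpha / sum_{g in S} r_g^alpha
    P_out(i) = |{j <= i : g_j not in S}| / (N - |S|)

Being rank-based, the score transfers to an independent cohort without
re-estimating anything from the discovery data. Cohort-level range
normalization (divide by max - min of the raw score matrix) is applied
by default.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["ssgsea_sample_score", "score_matrix", "SSGSEAScorer"]


def _rank_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting genes by expression descending, ties by gene id."""
    return np.lexsort((gene_ids, -values))


def ssgsea_sample_score(
    expression: pd.Series,
    gene_set: Sequence[str],
    alpha: float = 0.25,
) -> float:
    """ssGSEA enrichment score of one gene set in one sample."""
    gene_ids = np.asarray(expression.index.astype(str))
    values = expression.to_numpy(dtype=float)
    in_set = np.isin(gene_ids, list(gene_set))
    n, s = len(gene_ids), int(in_set.sum())
    if s == 0:
        raise ValueError("gene set shares no genes with the expression universe")
    if s == n:
        raise ValueError("gene set equals the expression universe")
    order = _rank_order(values, gene_ids)
    return float(_es_from_order(in_set[order], n, s, alpha))


def _es_from_order(in_sorted: np.ndarray, n: int, s: int, alpha: float) -> float:
    weights = (n - np.arange(n, dtype=float)) ** alpha  # rank from bottom
    w_in = np.where(in_sorted, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_sorted) / (n - s)
    return np.sum(p_in - p_out)


def score_matrix(
    expr: pd.DataFrame,
    modules: Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Samples x modules ssGSEA score matrix.

    Module genes absent from ``expr`` are ignored; a module with no
    genes present yields a column of NaN with a warning (the replication
    use case, where universes differ). With ``normalize``, all raw
    scores are divided by the global (max - min) of the matrix.
    """
    if not modules:
        raise ValueError("no modules supplied")
    gene_ids = np.asarray(expr.columns.astype(str))
    X = expr.to_numpy(dtype=float)
    n_samples, n_genes = X.shape
    orders = [_rank_order(X[i], gene_ids) for i in range(n_samples)]

    out = np.full((n_samples, len(modules)), np.nan)
    for j, (name, genes) in enumerate(modules.items()):
        in_set = np.isin(gene_ids, list(genes))
        s = int(in_set.sum())
        if s == 0:
            warnings.warn(f"module {name!r} has no genes in the expression matrix",
                          RuntimeWarning, stacklevel=2)
            continue
        if s == n_genes:
            raise ValueError(f"module {name!r} covers the whole gene universe")
        for i in range(n_samples):
            out[i, j] = _es_from_order(in_set[orders[i]], n_genes, s, alpha)

    result = pd.DataFrame(out, index=expr.index, columns=list(modules))
    if normalize:
        finite = result.to_numpy()[np.isfinite(result.to_numpy())]
        if finite.size:
            span = finite.max() - finite.min()
            if span > 0:
                result = result / span
    return result


class SSGSEAScorer(BaseEstimator, TransformerMixin):
    """Project expression onto module-level enrichment scores.

    Parameters
    ----------
    gene_sets : mapping of module name -> gene ids
        The modules to score (typically ``CoexpressionModuleDetector.gene_sets_``).
    alpha : float
        Rank-weight exponent (0.25, the conventional ssGSEA default).
    normalize : bool
        Divide raw scores by the global range of the transformed matrix.
        The normalization is computed per transformed cohort, so an
        external cohort is scored without reference to the discovery
        data.
    """

    def __init__(
        self,
        gene_sets: Mapping[str, Sequence[str]] | None = None,
        alpha: float = 0.25,
        normalize: bool = True,
    ):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X=None, y=None):
        if not self.gene_sets:
            raise ValueError("gene_sets must be provided")
        self.gene_sets_ = {k: list(v) for k, v in self.gene_sets.items()}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "gene_sets_"):
            self.fit()
        return score_matrix(X, self.gene_sets_, alpha=self.alpha, normalize=self.normalize)
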