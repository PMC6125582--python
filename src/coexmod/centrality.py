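"""Gene network centrality vs univariate phenotype importance.

Eigenvector centrality of each gene in the (thresholded, weighted)
co-expression adjacency is compared with the gene's univariate
importance for the diagnosis — the negative natural log of its
BH-adjusted logistic-regression p-value. Within each module an OLS of
importance on centrality summarizes the "hub genes matter more" signal
as an R-squared, and a hypergeometric test asks whether a module is
over-represented among the top-k most significant genes.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix
from scipy.stats import chi2, hypergeom

from .association import bh_adjust

__all__ = [
    "eigenvector_centrality",
    "univariate_importance",
    "module_centrality_correlation",
    "top_gene_enrichment",
]

_P_FLOOR = 1e-300


def eigenvector_centrality(
    adj: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Non-negative principal eigenvector of a symmetric adjacency.

    Power iteration on the largest connected component (by node count),
    zeros elsewhere; the result is normalized to unit Euclidean norm.
    Scale-invariant in the adjacency.
    """
    A = np.asarray(adj, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    if not (A > 0).any():
        raise ValueError("adjacency has no edges")

    n_comp, comp = connected_components(csr_matrix(A > 0), directed=False)
    sizes = np.bincount(comp)
    main = int(np.argmax(sizes))
    if n_comp > 1:
        warnings.warn(
            f"adjacency has {n_comp} connected components (sizes {sorted(sizes, reverse=True)[:5]}...); "
            "centrality computed on the largest, zeros elsewhere",
            RuntimeWarning,
            stacklevel=2,
        )
    idx = np.flatnonzero(comp == main)
    S = A[np.ix_(idx, idx)].copy()
    # diagonal shift: same principal eigenvector, but keeps the power
    # iteration from oscillating on bipartite spectra (eigenvalues +-lam)
    shift = S.sum(axis=1).max()
    S[np.diag_indices_from(S)] += shift

    v = np.full(len(idx), 1.0 / np.sqrt(len(idx)))
    for _ in range(max_iter):
        w = S @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("power iteration collapsed to zero")
        w /= norm
        if np.linalg.norm(w - v) <= tol * np.linalg.norm(v):
            v = w
            break
        v = w
    else:
        raise RuntimeError(f"power iteration did not converge in {max_iter} iterations")

    out = np.zeros(A.shape[0])
    out[idx] = np.abs(v)
    out /= np.linalg.norm(out)
    return out


def univariate_importance(
    expr: pd.DataFrame,
    diagnosis: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Per-gene logistic regression of diagnosis on expression.

    Returns per gene: Wald two-sided ``p_raw``, BH-adjusted ``p_adj``
    across all genes, and importance ``s = -ln(p_adj)``. Genes with
    perfect separation fall back to a likelihood-ratio test against the
    intercept-only model and are flagged in ``separation``.
    """
    y = np.asarray(diagnosis)
    if y.dtype.kind in "OUS":
        levels = sorted(pd.unique(y))
        if len(levels) != 2:
            raise ValueError(f"diagnosis must be binary, got levels {levels}")
        y = (y == levels[1]).astype(float)
    else:
        y = y.astype(float)
    if len(np.unique(y)) != 2:
        raise ValueError("both diagnosis classes must be present")

    n = len(y)
    pbar = y.mean()
    llnull = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    X0 = np.ones((n, 2))
    p_raw = np.empty(expr.shape[1])
    separated = np.zeros(expr.shape[1], dtype=bool)
    for j, gene in enumerate(expr.columns):
        X0[:, 1] = expr.iloc[:, j].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X0).fit(disp=0, maxiter=100)
            if not np.all(np.isfinite(fit.bse)) or fit.bse[1] > 1e6:
                raise ValueError("separation")
            p_raw[j] = fit.pvalues[1]
        except Exception:
            # perfect separation: the saturated log-likelihood is 0
            lr = -2.0 * llnull
            p_raw[j] = chi2.sf(lr, df=1)
            separated[j] = True
    p_adj = bh_adjust(p_raw)
    s = -np.log(np.maximum(p_adj, _P_FLOOR))
    return pd.DataFrame(
        {"p_raw": p_raw, "p_adj": p_adj, "s": s, "separation": separated},
        index=expr.columns,
    )


def module_centrality_correlation(
    importance: pd.Series,
    centrality: pd.Series,
    labels: pd.Series,
) -> pd.Series:
    """Per-module R-squared of importance regressed on centrality.

    Modules with fewer than 3 genes or zero-variance centrality give
    NaN. Label 0 (unassigned genes) is skipped.
    """
    importance = importance.reindex(labels.index)
    centrality = centrality.reindex(labels.index)
    out = {}
    for lab in sorted(set(labels) - {0}):
        mask = labels == lab
        if mask.sum() < 3:
            out[lab] = np.nan
            continue
        x = centrality[mask].to_numpy(dtype=float)
        y = importance[mask].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            out[lab] = np.nan
            continue
        r = np.corrcoef(x, y)[0, 1]
        out[lab] = r * r
    return pd.Series(out, name="r_squared")


def top_gene_enrichment(
    labels: pd.Series,
    gene_p: pd.Series,
    top_k: int = 100,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each module in the top-k genes.

    Genes are ranked by p ascending (ties by gene id); for module ``i``
    with ``K_i`` genes in a universe of ``N``, observing ``x_i`` of them
    among the top ``k`` has upper-tail inclusive probability
    ``P(X >= x_i)`` with ``X ~ Hypergeometric(N, K_i, k)``.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    gene_p = gene_p.reindex(labels.index)
    N = len(labels)
    if top_k > N:
        raise ValueError(f"top_k={top_k} exceeds the {N}-gene universe")
    order = np.lexsort((labels.index.astype(str), gene_p.to_numpy()))
    top = set(labels.index[order[:top_k]])
    rows = []
    for lab in sorted(set(labels) - {0}):
        members = labels.index[labels == lab]
        K = len(members)
        x = sum(g in top for g in members)
        p = float(hypergeom.sf(x - 1, N, K, top_k))
        rows.append({"module": lab, "size": K, "x_top": x, "p_hypergeom": p})
    return pd.DataFrame(rows).set_index("module")


def centrality_report(
    adjacency: np.ndarray,
    gene_ids: Sequence[str],
    expr: pd.DataFrame,
    diagnosis: pd.Series,
    labels: pd.Series,
    top_k: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: per-gene and per-module centrality tables."""
    cent = pd.Series(
        eigenvector_centrality(adjacency), index=pd.Index(gene_ids), name="centrality"
    )
    imp = univariate_importance(expr[list(gene_ids)], diagnosis)
    per_gene = pd.concat([cent, imp, labels.rename("module")], axis=1)
    r2 = module_centrality_correlation(imp["s"], cent, labels)
    enrich = top_gene_enrichment(labels, imp["p_raw"], top_k=top_k)
    per_module = enrich.join(r2)
    return per_gene, per_module
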