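"""Count preprocessing: low-count filter, logCPM, outliers, batch, COV.

The stages mirror a standard bulk RNA-Seq hygiene pass before network
construction:

1. remove genes without >= ``min_samples`` samples reaching a per-sample
   read threshold that scales with library size (2 reads for the
   smallest library up to 7 for the largest, linear in library-size
   rank);
2. normalize to log2 counts per million (logCPM) with a prior count
   (no GC/gene-length adjustment: the matrix is annotation-free);
3. drop samples whose angle-based outlier factor (ABOF) falls below a
   threshold — geometric outliers subtend unusually stable angles;
4. regress out batch indicator contrasts per gene, keeping covariate
   effects and gene means;
5. drop genes whose coefficient of variation on the unlogged CPM scale
   exceeds a threshold (high-COV genes reflect technical variability).

``RNASeqPreprocessor`` chains the stages and records provenance (which
rule removed which gene/sample) for the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, OutlierMixin

__all__ = [
    "filter_low_counts",
    "logcpm",
    "cpm",
    "abof_scores",
    "abof_report",
    "remove_batch_effect",
    "cov_filter",
    "tmm_factors",
    "AngleBasedOutlierDetector",
    "RNASeqPreprocessor",
    "OutlierReport",
]


def _library_sizes(counts: pd.DataFrame, library_sizes: pd.Series | None) -> pd.Series:
    if library_sizes is None:
        return counts.sum(axis=0).astype(float)
    lib = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if lib.isna().any():
        missing = list(lib.index[lib.isna()])
        raise ValueError(f"library sizes missing for samples {missing}")
    return lib


def low_count_thresholds(
    library_sizes: pd.Series, min_reads_range: tuple[int, int] = (2, 7)
) -> pd.Series:
    """Per-sample read thresholds, linear in library-size rank.

    The smallest library gets ``min_reads_range[0]`` reads, the largest
    ``min_reads_range[1]``, intermediate libraries interpolate linearly
    over their rank and round to the nearest integer.
    """
    lo, hi = min_reads_range
    n = len(library_sizes)
    order = np.argsort(library_sizes.to_numpy(), kind="stable")
    rank = np.empty(n, dtype=float)
    rank[order] = np.arange(n)
    frac = rank / (n - 1) if n > 1 else np.zeros(n)
    t = np.floor(lo + (hi - lo) * frac + 0.5).astype(int)
    return pd.Series(t, index=library_sizes.index, name="min_reads")


def filter_low_counts(
    counts: pd.DataFrame,
    min_samples: int = 15,
    min_reads_range: tuple[int, int] = (2, 7),
    library_sizes: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep genes detected at the library-size-dependent read threshold.

    A gene is retained when at least ``min_samples`` samples have reads
    greater than or equal to their per-sample threshold. Returns the
    filtered matrix and the removed gene ids. Idempotent for fixed
    library sizes (thresholds depend on library-size ranks only).
    """
    if counts.empty:
        raise ValueError("empty count matrix")
    n_samples = counts.shape[1]
    if min_samples > n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {n_samples} available samples"
        )
    lib = _library_sizes(counts, library_sizes)
    t = low_count_thresholds(lib, min_reads_range)
    detected = (counts.to_numpy() >= t.to_numpy()[None, :]).sum(axis=1)
    keep = detected >= min_samples
    removed = list(counts.index[~keep])
    return counts.loc[keep], removed


def logcpm(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million, samples x genes.

    ``log2((count + prior) / (library + 2 * prior) * 1e6)``.
    """
    lib = _library_sizes(counts, library_sizes)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero or negative library size for samples {bad}")
    values = np.log2(
        (counts.to_numpy(dtype=float) + prior)
        / (lib.to_numpy()[None, :] + 2.0 * prior)
        * 1.0e6
    )
    return pd.DataFrame(values.T, index=counts.columns, columns=counts.index)


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Unlogged counts-per-million, samples x genes."""
    lib = _library_sizes(counts, library_sizes)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero or negative library size for samples {bad}")
    values = counts.to_numpy(dtype=float) / lib.to_numpy()[None, :] * 1.0e6
    return pd.DataFrame(values.T, index=counts.columns, columns=counts.index)


@dataclass
class OutlierReport:
    abof: pd.Series
    threshold: float
    removed: list[str] = field(default_factory=list)


def abof_scores(expr: pd.DataFrame, standardize: bool = True) -> pd.Series:
    """Angle-based outlier factor per sample.

    For sample ``p``, ABOF(p) is the variance over all unordered pairs
    ``(x, y)`` of the other samples of
    ``<p-x, p-y> / (||p-x||^2 * ||p-y||^2)``. Points deep inside the
    cloud see pairs under widely varying angles (large variance);
    outliers see everything in roughly one direction (small variance).
    Pairs involving a point coincident with ``p`` are skipped.

    With ``standardize`` each gene is z-scored and the matrix is then
    scaled so the mean pairwise squared distance is 1. The second step
    makes the factor dimensionless — the raw quantity shrinks like the
    inverse fourth power of typical distances, which grow with gene
    count — so one absolute threshold (0.001) is meaningful regardless
    of how many genes survived filtering.
    """
    X = expr.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("ABOF needs at least 3 samples")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
        msd = pdist(X, "sqeuclidean").mean()
        if msd == 0:
            raise ValueError("all samples are identical; ABOF undefined")
        X = X / np.sqrt(msd)
    out = np.empty(n)
    for i in range(n):
        D = np.delete(X, i, axis=0) - X[i]
        d2 = np.einsum("ij,ij->i", D, D)
        valid = d2 > 0
        D, d2 = D[valid], d2[valid]
        m = len(d2)
        if m < 2:
            raise ValueError(f"all pairs degenerate for sample {expr.index[i]!r}")
        G = D @ D.T
        W = G / np.outer(d2, d2)
        iu = np.triu_indices(m, k=1)
        out[i] = np.var(W[iu])
    return pd.Series(out, index=expr.index, name="abof")


def abof_report(
    expr: pd.DataFrame,
    threshold: float = 0.001,
    relative_threshold: float = 0.1,
    standardize: bool = True,
) -> OutlierReport:
    """Score samples and flag those with a distinctly small factor.

    The effective cutoff is ``min(threshold, relative_threshold *
    median ABOF)``: a sample must fall below the absolute threshold
    *and* be an order of magnitude below the cohort's typical factor.
    The guard matters because the factor's overall scale shrinks with
    the data's effective dimension — a weakly correlated cohort can sit
    entirely below any fixed absolute cutoff without containing a
    single geometric outlier.
    """
    scores = abof_scores(expr, standardize=standardize)
    effective = min(threshold, relative_threshold * float(scores.median()))
    removed = list(scores.index[scores < effective])
    return OutlierReport(abof=scores, threshold=effective, removed=removed)


class AngleBasedOutlierDetector(BaseEstimator, OutlierMixin):
    """Flag samples with an exceptionally small angle-based outlier factor.

    Parameters
    ----------
    threshold : float
        Absolute cutoff (default 0.001 on per-gene standardized,
        distance-normalized data).
    relative_threshold : float
        Additional guard: the effective cutoff is
        ``min(threshold, relative_threshold * median ABOF)``.
    standardize : bool
        Z-score each gene before computing angles, so genes with large
        scales do not dominate.

    Attributes
    ----------
    abof_ : pandas.Series
        Factor per sample.
    threshold_ : float
        The effective (resolved) cutoff.
    outliers_ : list of sample ids flagged.
    """

    def __init__(
        self,
        threshold: float = 0.001,
        relative_threshold: float = 0.1,
        standardize: bool = True,
    ):
        self.threshold = threshold
        self.relative_threshold = relative_threshold
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y=None):
        report = abof_report(
            X,
            threshold=self.threshold,
            relative_threshold=self.relative_threshold,
            standardize=self.standardize,
        )
        self.abof_ = report.abof
        self.threshold_ = report.threshold
        self.outliers_ = report.removed
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        """-1 for outliers, +1 for inliers."""
        self.fit(X)
        return np.where(self.abof_ < self.threshold_, -1, 1)


def _batch_contrasts(batch: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero contrasts for a categorical batch variable."""
    levels = sorted(pd.unique(batch))
    if len(levels) < 2:
        return np.empty((len(batch), 0)), levels
    B = np.zeros((len(batch), len(levels) - 1))
    codes = pd.Categorical(batch, categories=levels).codes
    for j in range(len(levels) - 1):
        B[codes == j, j] = 1.0
    B[codes == len(levels) - 1, :] = -1.0
    return B, levels


def remove_batch_effect(
    expr: pd.DataFrame,
    batch: pd.Series,
    keep_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Subtract the per-gene batch component estimated by OLS.

    Per gene, expression is regressed on an intercept, the kept
    covariates and sum-to-zero batch contrasts; only the fitted batch
    component (mean-centred, so the per-gene grand mean is preserved
    exactly even for unbalanced batches) is subtracted. With a single
    batch the input is returned unchanged.
    """
    batch = pd.Series(batch).reindex(expr.index)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    counts = batch.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"batch levels with fewer than 2 samples: {small}")
    B, levels = _batch_contrasts(batch)
    if B.shape[1] == 0:
        return expr.copy()

    n = len(expr)
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    if keep_covariates is not None:
        C = pd.DataFrame(keep_covariates).reindex(expr.index)
        if C.isna().any().any():
            raise ValueError("covariates missing for some samples")
        parts.append(C.to_numpy(dtype=float))
        names += [str(c) for c in C.columns]
    parts.append(B)
    names += [f"batch[{lvl}]" for lvl in levels[:-1]]
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular design: batch is confounded with a kept covariate "
            f"(columns: {names})"
        )
    beta, *_ = np.linalg.lstsq(X, expr.to_numpy(dtype=float), rcond=None)
    batch_cols = slice(X.shape[1] - B.shape[1], X.shape[1])
    component = B @ beta[batch_cols]
    component -= component.mean(axis=0, keepdims=True)
    return pd.DataFrame(
        expr.to_numpy(dtype=float) - component, index=expr.index, columns=expr.columns
    )


def cov_filter(
    cpm_matrix: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.Series, pd.DataFrame]:
    """Coefficient-of-variation gene filter on the unlogged CPM scale.

    COV = sample standard deviation / mean across samples, per gene.
    Genes with COV > threshold (or with zero mean, where COV is
    undefined) are flagged for removal. Returns (keep mask per gene,
    report with COV and removal reason).
    """
    values = cpm_matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean > 0, sd / mean, np.nan)
    keep = (mean > 0) & (cov <= threshold)
    reason = np.where(mean <= 0, "zero-mean", np.where(cov > threshold, "high-cov", ""))
    report = pd.DataFrame(
        {"cov": cov, "kept": keep, "reason": reason}, index=cpm_matrix.columns
    )
    return pd.Series(keep, index=cpm_matrix.columns, name="kept"), report


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (diagnostic only).

    Reported alongside the outlier analysis — samples needing extreme
    scaling usually are the geometric outliers — but never applied:
    logCPM uses raw library sizes.
    """
    lib = _library_sizes(counts, library_sizes)
    X = counts.to_numpy(dtype=float)
    p = X / lib.to_numpy()[None, :]
    q75 = np.quantile(p, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = p[:, ref_idx]
    log_factors = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        obs = p[:, j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() < 10:
            continue
        m = np.log2(obs[ok] / ref[ok])
        a = 0.5 * np.log2(obs[ok] * ref[ok])
        w = 1.0 / obs[ok] / lib.iloc[j] + 1.0 / ref[ok] / lib.iloc[ref_idx]
        keep = (
            (m >= np.quantile(m, trim_m))
            & (m <= np.quantile(m, 1 - trim_m))
            & (a >= np.quantile(a, trim_a))
            & (a <= np.quantile(a, 1 - trim_a))
        )
        if keep.any():
            log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    log_factors -= log_factors.mean()
    return pd.Series(2.0**log_factors, index=counts.columns, name="tmm_factor")


class RNASeqPreprocessor(BaseEstimator):
    """Full preprocessing chain with provenance bookkeeping.

    Order: low-count filter -> logCPM -> ABOF outlier removal -> batch
    removal -> COV filter. ``fit_transform`` consumes a genes x samples
    count matrix plus a phenotype table and returns the final samples x
    genes logCPM matrix.

    Attributes (after ``fit_transform``)
    ------------------------------------
    library_sizes_ : per-sample totals of the raw matrix
    removed_low_count_, removed_high_cov_ : gene id lists
    removed_outliers_ : sample id list
    abof_ : ABOF per sample
    tmm_factors_ : diagnostic TMM factors (never applied)
    provenance_ : dict summarizing every filter (counts in/out, rules)
    """

    def __init__(
        self,
        min_samples: int = 15,
        min_reads_range: tuple[int, int] = (2, 7),
        prior: float = 0.5,
        abof_threshold: float = 0.001,
        cov_threshold: float = 0.8,
        batch_col: str | None = "batch",
    ):
        self.min_samples = min_samples
        self.min_reads_range = min_reads_range
        self.prior = prior
        self.abof_threshold = abof_threshold
        self.cov_threshold = cov_threshold
        self.batch_col = batch_col

    def fit_transform(
        self,
        counts: pd.DataFrame,
        phenotypes: pd.DataFrame | None = None,
        keep_covariates: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        n_genes_in, n_samples_in = counts.shape
        self.library_sizes_ = counts.sum(axis=0).astype(float)

        kept_counts, self.removed_low_count_ = filter_low_counts(
            counts,
            min_samples=self.min_samples,
            min_reads_range=self.min_reads_range,
            library_sizes=self.library_sizes_,
        )
        expr = logcpm(kept_counts, self.library_sizes_, prior=self.prior)

        detector = AngleBasedOutlierDetector(threshold=self.abof_threshold)
        detector.fit(expr)
        self.abof_ = detector.abof_
        self.abof_threshold_ = detector.threshold_
        self.removed_outliers_ = detector.outliers_
        keep_samples = expr.index.difference(self.removed_outliers_, sort=False)
        expr = expr.loc[keep_samples]
        self.tmm_factors_ = tmm_factors(kept_counts, self.library_sizes_)

        if self.batch_col is not None and phenotypes is not None:
            batch = phenotypes.loc[keep_samples, self.batch_col]
            if batch.nunique() > 1:
                expr = remove_batch_effect(expr, batch, keep_covariates)

        cpm_kept = cpm(kept_counts[keep_samples], self.library_sizes_[keep_samples])
        keep_mask, self.cov_report_ = cov_filter(cpm_kept, self.cov_threshold)
        self.removed_high_cov_ = list(keep_mask.index[~keep_mask])
        expr = expr.loc[:, keep_mask[keep_mask].index]

        self.expression_ = expr
        self.provenance_ = {
            "n_genes_in": int(n_genes_in),
            "n_samples_in": int(n_samples_in),
            "low_count": {
                "rule": f">= {self.min_samples} samples with reads >= t(library rank), "
                f"t in {list(self.min_reads_range)}",
                "n_removed": len(self.removed_low_count_),
                "removed": list(self.removed_low_count_),
            },
            "normalized_genes": int(n_genes_in - len(self.removed_low_count_)),
            "outliers": {
                "rule": f"ABOF < {self.abof_threshold_:.3g} "
                f"(min of {self.abof_threshold} and 0.1 x median)",
                "n_removed": len(self.removed_outliers_),
                "removed": list(self.removed_outliers_),
            },
            "high_cov": {
                "rule": f"CPM coefficient of variation > {self.cov_threshold}",
                "n_removed": len(self.removed_high_cov_),
                "removed": list(self.removed_high_cov_),
            },
            "n_genes_out": int(expr.shape[1]),
            "n_samples_out": int(expr.shape[0]),
        }
        # arithmetic identity: in - low_count - high_cov = out
        assert (
            n_genes_in
            - len(self.removed_low_count_)
            - len(self.removed_high_cov_)
            == expr.shape[1]
        )
        return expr
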