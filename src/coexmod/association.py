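"""Covariate-adjusted association of module scores with trait severity.

Per module, the (z-scored) severity trait is regressed by ordinary least
squares on that module's enrichment score plus covariates (sex, age,
BMI, batch; optionally smoking). The per-module slope p-values are
Benjamini-Hochberg adjusted within the module family. A smoking
sensitivity model is compared to the base model by BIC, and any sample
subset (e.g. a single self-reported ancestry) can be re-fit for a
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "scale_trait",
    "bh_adjust",
    "build_covariates",
    "fit_module_models",
    "compare_bic",
    "subset_sensitivity",
    "ModuleTraitRegression",
]


def scale_trait(values: pd.Series | np.ndarray) -> np.ndarray:
    """Z-score a trait vector (sample standard deviation)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("trait must be non-empty and finite")
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        raise ValueError("trait has zero variance")
    return (x - x.mean()) / sd


def bh_adjust(p: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values.

    ``adjusted_(k) = min_{j >= k} min(1, p_(j) * m / j)`` over the sorted
    p-values, mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def build_covariates(
    phenotypes: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "age", "bmi", "batch"),
    add_smoking: bool = False,
) -> pd.DataFrame:
    """Numeric design columns from a phenotype table.

    Categorical columns (sex, batch, smoking, anything non-numeric)
    become 0/1 indicator contrasts with the first level dropped.
    """
    cols = list(covariates) + (["smoking"] if add_smoking else [])
    missing = [c for c in cols if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table lacks covariate columns {missing}")
    parts = []
    for col in cols:
        series = phenotypes[col]
        if pd.api.types.is_numeric_dtype(series):
            parts.append(series.astype(float))
        else:
            dummies = pd.get_dummies(series, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(names[j])
        raise ValueError(f"singular design; collinear columns: {collinear}")


def fit_module_models(
    scores: pd.DataFrame,
    trait: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of the trait on each module score plus covariates.

    Returns one row per module: ``beta``, ``se``, ``t``, ``p_raw``,
    ``p_adj`` (BH within the module family), ``n``, ``bic``. Samples
    with any missing value are dropped listwise.
    """
    trait = pd.Series(np.asarray(trait, dtype=float), index=scores.index, name="trait")
    frames = [scores, trait]
    if covariates is not None:
        covariates = covariates.reindex(scores.index)
        frames.append(covariates)
    data = pd.concat(frames, axis=1)
    data = data.dropna()
    if data.empty:
        raise ValueError("no complete cases after listwise deletion")
    y = data["trait"].to_numpy()
    cov_cols = list(covariates.columns) if covariates is not None else []
    n_params = 2 + len(cov_cols)
    if len(data) <= n_params:
        raise ValueError(
            f"n={len(data)} complete cases cannot fit {n_params} parameters"
        )

    rows = []
    for module in scores.columns:
        X = np.column_stack(
            [np.ones(len(data)), data[module].to_numpy()]
            + [data[c].to_numpy(dtype=float) for c in cov_cols]
        )
        _check_full_rank(X, ["intercept", str(module), *cov_cols])
        fit = sm.OLS(y, X).fit()
        rows.append(
            {
                "module": module,
                "beta": fit.params[1],
                "se": fit.bse[1],
                "t": fit.tvalues[1],
                "p_raw": fit.pvalues[1],
                "n": int(fit.nobs),
                "bic": fit.bic,
            }
        )
    table = pd.DataFrame(rows).set_index("module")
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table.attrs["covariates"] = cov_cols
    return table[["beta", "se", "t", "p_raw", "p_adj", "n", "bic"]]


@dataclass
class BICComparison:
    chosen: int  # 0 = first (without), 1 = second (with)
    bic: tuple[float, float]
    tie: bool


def compare_bic(model_without, model_with) -> BICComparison:
    """Pick the model with the smaller BIC (ties keep the first).

    Accepts statsmodels results or anything exposing ``bic`` and
    ``nobs``; both models must be fit on the same samples.
    """
    n0, n1 = int(model_without.nobs), int(model_with.nobs)
    if n0 != n1:
        raise ValueError(f"models fit on different n: {n0} vs {n1}")
    b0, b1 = float(model_without.bic), float(model_with.bic)
    tie = b0 == b1
    return BICComparison(chosen=0 if b0 <= b1 else 1, bic=(b0, b1), tie=tie)


def subset_sensitivity(
    scores: pd.DataFrame,
    trait: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None,
    mask: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Re-fit the module models on a sample subset (sensitivity analysis)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty sample subset")
    trait = pd.Series(np.asarray(trait, dtype=float), index=scores.index)
    return fit_module_models(
        scores.loc[mask],
        trait.loc[mask],
        covariates.loc[mask] if covariates is not None else None,
    )


class ModuleTraitRegression(BaseEstimator):
    """Module-score vs trait association with FDR control.

    Parameters
    ----------
    covariates : sequence of phenotype column names used as adjustment
        variables (categoricals become indicator contrasts).
    add_smoking : bool
        Also fit the smoking-augmented sensitivity model and compare by
        BIC.
    fdr : float
        BH-adjusted significance threshold for flagging modules.
    scale : bool
        Z-score the trait before fitting.

    Attributes
    ----------
    results_ : association table of the base model
    significant_modules_ : modules with ``p_adj < fdr``
    smoking_results_, smoking_bic_choice_ : sensitivity model outputs
        (only when ``add_smoking``)
    """

    def __init__(
        self,
        covariates: Sequence[str] = ("sex", "age", "bmi", "batch"),
        add_smoking: bool = False,
        fdr: float = 0.05,
        scale: bool = True,
    ):
        self.covariates = covariates
        self.add_smoking = add_smoking
        self.fdr = fdr
        self.scale = scale

    def fit(self, X: pd.DataFrame, y, phenotypes: pd.DataFrame | None = None):
        trait = np.asarray(y, dtype=float)
        if self.scale:
            trait = scale_trait(trait)
        cov = (
            build_covariates(phenotypes.reindex(X.index), self.covariates)
            if phenotypes is not None and self.covariates
            else None
        )
        self.results_ = fit_module_models(X, trait, cov)
        self.significant_modules_ = list(
            self.results_.index[self.results_["p_adj"] < self.fdr]
        )
        if self.add_smoking and phenotypes is not None:
            cov_smoke = build_covariates(
                phenotypes.reindex(X.index), self.covariates, add_smoking=True
            )
            self.smoking_results_ = fit_module_models(X, trait, cov_smoke)
            # compare overall fit via summed per-module BIC on shared n
            base = self.results_
            smoke = self.smoking_results_

            class _Agg:
                def __init__(self, table):
                    self.bic = float(table["bic"].sum())
                    self.nobs = int(table["n"].iloc[0])

            self.smoking_bic_choice_ = compare_bic(_Agg(base), _Agg(smoke))
        return self
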