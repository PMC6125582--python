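"""Replication of discovered modules in an independent cohort.

Module gene sets from the discovery cohort are intersected with the
external cohort's gene universe, scored with ssGSEA on the external
expression alone (rank-based, so nothing is carried over from
discovery), and tested by logistic regression of diagnosis on the
module score with sex, age and BMI as covariates.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import _check_full_rank, build_covariates
from .scores import score_matrix

__all__ = ["restrict_modules", "replicate"]


def restrict_modules(
    modules: Mapping[str, Sequence[str]],
    external_universe: Sequence[str],
    floor: int = 10,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Intersect each module with an external gene universe.

    Returns the restricted gene sets and a report with the overlap count
    and fraction per module; modules whose overlap falls below ``floor``
    genes are flagged (and excluded from the restricted sets).
    """
    universe = set(map(str, external_universe))
    restricted: dict[str, list[str]] = {}
    rows = []
    for name, genes in modules.items():
        genes = list(genes)
        present = [g for g in genes if str(g) in universe]
        fraction = len(present) / len(genes) if genes else np.nan
        flagged = len(present) < floor
        rows.append(
            {
                "module": name,
                "n_genes": len(genes),
                "n_overlap": len(present),
                "fraction": fraction,
                "below_floor": flagged,
            }
        )
        if flagged:
            warnings.warn(
                f"module {name!r} keeps only {len(present)} genes in the external "
                f"universe (floor {floor}); excluded from replication",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            restricted[name] = present
    report = pd.DataFrame(rows).set_index("module")
    if report["n_overlap"].sum() == 0:
        raise ValueError("no module gene overlaps the external universe")
    return restricted, report


def replicate(
    external_expr: pd.DataFrame,
    modules: Mapping[str, Sequence[str]],
    diagnosis: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Logistic regression of diagnosis on each module's external score.

    ssGSEA scores are computed within the external cohort's own gene
    universe. Returns per module: log-odds ``beta``, ``se``, Wald
    two-sided ``p`` (no multiplicity adjustment across the small
    replication family), and ``n``.
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

    scores = score_matrix(external_expr, modules, alpha=alpha, normalize=True)
    cov_arr = None
    cov_names: list[str] = []
    if covariates is not None:
        covariates = covariates.reindex(external_expr.index)
        cov_arr = covariates.to_numpy(dtype=float)
        cov_names = [str(c) for c in covariates.columns]

    rows = []
    for module in scores.columns:
        s = scores[module].to_numpy(dtype=float)
        if not np.all(np.isfinite(s)):
            rows.append({"module": module, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "n": 0})
            continue
        parts = [np.ones(len(s)), s]
        if cov_arr is not None:
            parts.extend(cov_arr.T)
        X = np.column_stack(parts)
        _check_full_rank(X, ["intercept", str(module), *cov_names])
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        rows.append(
            {
                "module": module,
                "beta": fit.params[1],
                "se": fit.bse[1],
                "p": fit.pvalues[1],
                "n": int(fit.nobs),
            }
        )
    return pd.DataFrame(rows).set_index("module")


def replication_analysis(
    external_expr: pd.DataFrame,
    modules: Mapping[str, Sequence[str]],
    phenotypes: pd.DataFrame,
    diagnosis_col: str = "diagnosis",
    covariate_cols: Sequence[str] = ("sex", "age", "bmi"),
    floor: int = 10,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """restrict_modules + replicate, joined into one report table."""
    restricted, overlap = restrict_modules(modules, external_expr.columns, floor=floor)
    phenotypes = phenotypes.reindex(external_expr.index)
    cov = build_covariates(phenotypes, covariate_cols) if covariate_cols else None
    tests = replicate(
        external_expr, restricted, phenotypes[diagnosis_col], cov, alpha=alpha
    )
    return overlap.join(tests, how="left")
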