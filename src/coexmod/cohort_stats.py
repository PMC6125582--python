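"""Group-comparison statistics for a cohort characteristics table.

Pearson and Yates-continuity-corrected chi-square tests on contingency
tables, and the pooled-variance two-sample t-test computed from summary
statistics — the tests behind a standard "Table 1" comparing cases and
controls on demographics. Both chi-square variants are reported for
2x2 tables, since published tables rarely say which correction was
used.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind_from_stats

__all__ = [
    "pearson_chi_square",
    "yates_chi_square",
    "pooled_t_test",
    "table_one",
]


def _clean_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    row_ok = t.sum(axis=1) > 0
    col_ok = t.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            "dropping zero-margin rows/columns before the chi-square test",
            RuntimeWarning,
            stacklevel=3,
        )
        t = t[row_ok][:, col_ok]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table needs at least 2 rows and 2 columns with positive margins")
    return t


def pearson_chi_square(table) -> tuple[float, int]:
    """Pearson chi-square without continuity correction.

    ``chi2 = sum (O - E)^2 / E`` with ``E = row * col / n``;
    ``df = (r - 1)(c - 1)``. Zero-margin rows/columns are dropped with a
    warning first.
    """
    t = _clean_table(table)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return chi2, df


def yates_chi_square(table) -> tuple[float, int]:
    """Yates-corrected chi-square for a 2x2 table.

    ``chi2 = n (|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d))``, clamped
    at 0 when ``|ad - bc| < n/2``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"Yates correction applies to 2x2 tables, got {t.shape}")
    (a, b), (c, d) = t
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("zero margin in 2x2 table")
    num = abs(a * d - b * c) - n / 2.0
    chi2 = float(n * max(num, 0.0) ** 2 / margins)
    return chi2, 1


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Pooled-variance two-sample t from summary statistics.

    Returns ``(t, df)`` with ``df = n1 + n2 - 2``; the sign follows
    ``mean1 - mean2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    result = ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(result.statistic), n1 + n2 - 2


def table_one(
    phenotypes: pd.DataFrame,
    group: str = "diagnosis",
    continuous: tuple[str, ...] = ("age", "bmi", "madrs"),
    categorical: tuple[str, ...] = ("sex", "sra", "smoking"),
) -> pd.DataFrame:
    """Cohort characteristics table with per-variable group tests.

    Continuous variables get a pooled t-test from the observed group
    summaries; categorical variables get the Pearson chi-square, plus
    the Yates-corrected value for 2x2 tables. Rows with missing values
    are analyzed on available data.
    """
    groups = phenotypes[group].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"grouping column {group!r} must have exactly 2 levels")
    g1, g2 = sorted(groups)
    rows = []
    for var in continuous:
        if var not in phenotypes.columns:
            continue
        sub = phenotypes[[group, var]].dropna()
        a = sub.loc[sub[group] == g1, var].astype(float)
        b = sub.loc[sub[group] == g2, var].astype(float)
        t, df = pooled_t_test(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
        rows.append(
            {"variable": var, "test": "t", "statistic": t, "df": df,
             "yates_statistic": np.nan,
             f"{g1}_summary": f"{a.mean():.1f} ({a.std(ddof=1):.2f})",
             f"{g2}_summary": f"{b.mean():.1f} ({b.std(ddof=1):.2f})"}
        )
    for var in categorical:
        if var not in phenotypes.columns:
            continue
        sub = phenotypes[[group, var]].dropna()
        table = pd.crosstab(sub[var], sub[group])
        chi2, df = pearson_chi_square(table.to_numpy())
        yates = np.nan
        if table.shape == (2, 2):
            yates, _ = yates_chi_square(table.to_numpy())
        rows.append(
            {"variable": var, "test": "chi2", "statistic": chi2, "df": df,
             "yates_statistic": yates,
             f"{g1}_summary": "/".join(map(str, table[g1].tolist())),
             f"{g2}_summary": "/".join(map(str, table[g2].tolist()))}
        )
    return pd.DataFrame(rows).set_index("variable")
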