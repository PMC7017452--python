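"""Cross-study fold-change concordance and cohort-table statistics.

In-silico validation compares per-gene log2 fold changes from two studies by
Spearman rank correlation and direction-of-change agreement. Cohort
demographic tables use Welch's t-test for continuous variables and Fisher's
exact test for categorical ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConcordanceResult:
    spearman_r: float
    spearman_p: float
    direction_agreement: float  # fraction in [0, 1]
    n: int
    n_zero_excluded: int  # pairs dropped from the agreement denominator


def fold_change_concordance(pairs: pd.DataFrame) -> ConcordanceResult:
    """Spearman correlation and sign agreement of matched log2 fold changes.

    ``pairs`` needs columns ``log2fc_a`` and ``log2fc_b`` (one row per
    gene). Agreement is the share of pairs with matching fold-change sign
    among pairs where both signs are non-zero; zero-FC pairs are excluded
    from that denominator and their count reported.
    """
    a = pairs["log2fc_a"].to_numpy(dtype=float)
    b = pairs["log2fc_b"].to_numpy(dtype=float)
    if len(a) < 3:
        raise ValueError("need at least 3 matched genes")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("fold changes must be finite")
    if np.all(a == 0) or np.all(b == 0):
        raise ValueError("all fold changes are zero in one study")
    rho, p = stats.spearmanr(a, b)
    nonzero = (a != 0) & (b != 0)
    n_excl = int(len(a) - nonzero.sum())
    agree = float(np.mean(np.sign(a[nonzero]) == np.sign(b[nonzero]))) if nonzero.any() else float("nan")
    return ConcordanceResult(float(rho), float(p), agree, len(a), n_excl)


def fisher_exact_2x2(table: list[list[int]] | np.ndarray) -> tuple[float, float]:
    """Sample odds ratio (ad/bc) and two-sided Fisher's exact p.

    The two-sided p sums, over all tables with the observed margins, the
    probabilities no greater than that of the observed table (the
    point-probability convention of mainstream statistical software). A zero
    margin gives p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or t.sum() == 0 or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be 2x2 non-negative integers with positive total")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    odds = float("inf") if b * c == 0 and a * d > 0 else (0.0 if b * c == 0 else (a * d) / (b * c))
    if 0 in (a + b, c + d, a + c, b + d):
        warnings.warn("a margin of the 2x2 table is zero; p set to 1")
        return odds, 1.0
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return odds, p


def welch_t_test(x: np.ndarray | list[float], y: np.ndarray | list[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        warnings.warn("both variances zero with unequal means; p = 0")
        return float("inf"), float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    sx, sy = vx / len(x), vy / len(y)
    df = (sx + sy) ** 2 / (sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def cohort_table(sheet_table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Demographic comparison table: one row per variable with its test p.

    Numeric columns are summarized as median (IQR) per group and compared
    with Welch's t-test; categorical columns as counts with Fisher's exact
    test (first-listed level versus the rest when more than two levels).
    """
    groups = list(pd.unique(sheet_table[group_col]))
    if len(groups) != 2:
        raise ValueError("cohort table requires exactly two groups")
    g0 = sheet_table[group_col] == groups[0]
    rows = []
    for col in sheet_table.columns:
        if col == group_col:
            continue
        series = sheet_table[col]
        if pd.api.types.is_numeric_dtype(series):
            x, y = series[g0].to_numpy(dtype=float), series[~g0].to_numpy(dtype=float)
            _, _, p = welch_t_test(x, y)
            summ = [
                f"{np.median(v):.2f} ({np.percentile(v, 25):.2f}-{np.percentile(v, 75):.2f})"
                for v in (x, y)
            ]
            rows.append((col, "welch_t", summ[0], summ[1], p))
        else:
            lev = sorted(series.astype(str).unique())[0]
            is_lev = series.astype(str) == lev
            tab = [
                [int((is_lev & g0).sum()), int((~is_lev & g0).sum())],
                [int((is_lev & ~g0).sum()), int((~is_lev & ~g0).sum())],
            ]
            _, p = fisher_exact_2x2(tab)
            rows.append(
                (col, "fisher_exact", f"{lev}: {tab[0][0]}/{int(g0.sum())}", f"{lev}: {tab[1][0]}/{int((~g0).sum())}", p)
            )
    return pd.DataFrame(
        rows, columns=["variable", "test", f"{groups[0]}", f"{groups[1]}", "p"]
    ).set_index("variable")
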