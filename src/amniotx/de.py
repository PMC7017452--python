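"""Covariate-adjusted linear models with empirical-Bayes moderated t-tests.

Each feature's log2 expression is fit by ordinary least squares against a
shared design matrix. Residual variances are shrunk toward a common prior
estimated by the method of moments on log s^2 (matching the scaled
log-chi-square distribution of residual variances), which lends the t
statistic d0 extra degrees of freedom — the classic moderated t. Calls are
gated jointly on the BH-adjusted p-value (q < 0.05) and a minimum fold
change (> 1.25-fold by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import MIDTRIMESTER, ExpressionSet, SampleSheet


@dataclass
class DesignMatrix:
    """Samples x coefficients design with a named tested contrast."""

    matrix: pd.DataFrame
    contrast: str

    def __post_init__(self) -> None:
        x = self.matrix.to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient (confounded factors)")
        if self.contrast not in self.matrix.columns:
            raise ValueError(f"contrast {self.contrast!r} not among design columns")


def build_design(
    sheet: SampleSheet,
    factors: list[str],
    contrast: str,
    reference: dict[str, str] | None = None,
) -> DesignMatrix:
    """Intercept + treatment-coded factors; continuous covariates untransformed.

    Categorical levels are sorted and the first is the reference — except
    that ``midtrimester`` is always the reference for the study-group factor
    when present, so the group contrast reads term relative to midtrimester.
    ``reference`` overrides the reference level per factor. The dummy column
    for factor ``f`` at level ``v`` is named ``f:v``. ``contrast`` may be a
    factor name (continuous or two-level categorical) or an explicit
    ``factor:level``.
    """
    reference = reference or {}
    missing = [f for f in factors if f not in sheet.table.columns]
    if missing:
        raise KeyError(f"factors absent from sample sheet: {missing}")
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(sheet.table))}
    colname_of_factor: dict[str, list[str]] = {}
    for f in factors:
        col = sheet.table[f]
        if pd.api.types.is_numeric_dtype(col):
            cols[f] = col.to_numpy(dtype=float)
            colname_of_factor[f] = [f]
        else:
            levels = sorted(pd.unique(col.astype(str)))
            if len(levels) < 2:
                raise ValueError(f"factor {f!r} is constant across samples")
            ref = reference.get(f, MIDTRIMESTER if MIDTRIMESTER in levels else levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not observed for factor {f!r}")
            levels = [ref] + [lev for lev in levels if lev != ref]
            names = []
            for lev in levels[1:]:
                name = f"{f}:{lev}"
                cols[name] = (col.astype(str) == lev).to_numpy(dtype=float)
                names.append(name)
            colname_of_factor[f] = names
    if contrast in cols:
        contrast_col = contrast
    elif contrast in colname_of_factor:
        names = colname_of_factor[contrast]
        if len(names) != 1:
            raise ValueError(
                f"factor {contrast!r} has >2 levels; specify the contrast as 'factor:level'"
            )
        contrast_col = names[0]
    else:
        raise ValueError(f"contrast {contrast!r} not among factors")
    matrix = pd.DataFrame(cols, index=sheet.table.index)
    return DesignMatrix(matrix, contrast_col)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the reciprocal)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to the residual variances.

    Matches the first two moments of log s^2 to the scaled log-chi-square
    distribution it follows under the hierarchical model: the excess of
    var(log s^2) over trigamma(df/2) identifies the prior degrees of
    freedom d0; the mean identifies the prior variance s0^2. A non-positive
    excess means no evidence of variance heterogeneity, giving d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.all(s2 <= 0):
        raise ValueError("all residual variances are zero; prior undefined")
    smallest = s2[s2 > 0].min()
    s2 = np.where(s2 > 0, s2, smallest)  # degenerate features borrow the floor
    z = np.log(s2)
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


@dataclass
class ModeratedFit:
    """Per-feature OLS fit with empirical-Bayes shrunken variances."""

    design: DesignMatrix
    coef: pd.DataFrame  # features x coefficients
    s2: pd.Series  # residual variances
    df_resid: float
    d0: float
    s02: float
    s2_post: pd.Series
    t: pd.Series
    p: pd.Series

    @property
    def contrast(self) -> str:
        return self.design.contrast

    @property
    def log2fc(self) -> pd.Series:
        return self.coef[self.design.contrast]

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_resid


def fit_moderated(
    es: ExpressionSet | pd.DataFrame,
    design: DesignMatrix,
    prior_df: float | None = None,
) -> ModeratedFit:
    """OLS per feature plus empirical-Bayes variance moderation.

    ``prior_df`` overrides the estimated prior degrees of freedom: 0 gives
    ordinary per-feature t-tests, ``inf`` fully pools to the prior variance.
    """
    values = es.values if isinstance(es, ExpressionSet) else es
    y = values.to_numpy(dtype=float)  # features x samples
    x = design.matrix.to_numpy(dtype=float)  # samples x coefs
    n, k = x.shape
    if y.shape[1] != n:
        raise ValueError("expression and design sample dimensions disagree")
    df_resid = float(n - k)
    if df_resid < 1:
        raise ValueError("residual degrees of freedom < 1")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv  # features x coefs
    resid = y - beta @ x.T
    s2 = (resid**2).sum(axis=1) / df_resid

    if prior_df is None:
        d0, s02 = estimate_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s02 = float(np.exp(np.mean(np.log(np.where(s2 > 0, s2, np.nan))))) if np.isfinite(d0) and d0 > 0 else 0.0
        if np.isinf(d0):
            _, s02 = estimate_prior(s2, df_resid)

    smallest = s2[s2 > 0].min() if np.any(s2 > 0) else 1.0
    s2_floor = np.where(s2 > 0, s2, smallest)
    if np.isinf(d0):
        s2_post = np.full_like(s2_floor, s02)
    elif d0 == 0:
        s2_post = s2_floor
    else:
        s2_post = (d0 * s02 + df_resid * s2_floor) / (d0 + df_resid)

    j = list(design.matrix.columns).index(design.contrast)
    v = float(xtx_inv[j, j])  # unscaled variance of the contrast coefficient
    t = beta[:, j] / np.sqrt(s2_post * v)
    df_total = min(d0 + df_resid, 1e9)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    idx = values.index
    return ModeratedFit(
        design=design,
        coef=pd.DataFrame(beta, index=idx, columns=design.matrix.columns),
        s2=pd.Series(s2, index=idx),
        df_resid=df_resid,
        d0=d0,
        s02=s02,
        s2_post=pd.Series(s2_post, index=idx),
        t=pd.Series(t, index=idx),
        p=pd.Series(p, index=idx),
    )


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_de(
    fit: ModeratedFit,
    fc_thresh: float = 1.25,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Significance calls: q < q_thresh AND |log2FC| > log2(fc_thresh)."""
    q = bh_adjust(fit.p.to_numpy())
    log2fc = fit.log2fc.to_numpy()
    significant = (q < q_thresh) & (np.abs(log2fc) > np.log2(fc_thresh))
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "feature_id": fit.p.index,
            "log2fc": log2fc,
            "t_mod": fit.t.to_numpy(),
            "df_total": fit.df_total,
            "p": fit.p.to_numpy(),
            "q": q,
            "significant": significant,
            "direction": direction,
        }
    ).set_index("feature_id")


def select_covariates(
    es: ExpressionSet,
    sheet: SampleSheet,
    candidates: list[str],
    q_thresh: float = 0.05,
) -> list[str]:
    """Retain a candidate covariate iff it shows a transcriptome-wide effect.

    A covariate is included when testing its own contrast (intercept + that
    covariate alone) yields at least one feature with q < ``q_thresh``.
    """
    kept = []
    for cand in candidates:
        try:
            design = build_design(sheet, [cand], cand)
        except ValueError:
            continue  # constant or confounded candidates cannot be assessed
        fit = fit_moderated(es, design)
        if np.any(bh_adjust(fit.p.to_numpy()) < q_thresh):
            kept.append(cand)
    return kept
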