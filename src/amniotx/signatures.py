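"""Cell-type and tissue signature tracking via reference-group Z-scores.

Each gene's log2 expression is standardized against the reference study
group (mean subtracted, divided by the reference-group SD), and the Z-scores
are averaged over the genes of a signature set — so every member gene
contributes equally regardless of its dynamic range. Signature scores are
compared between groups with the Wilcoxon rank-sum test and tracked along
gestational age with a linear trend plus a robust locally-quadratic LOESS
curve anchored at 16 weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionSet, GeneSetCollection, SampleSheet


@dataclass
class SignatureScore:
    """Per-sample averaged Z-score for one signature."""

    signature_name: str
    scores: pd.Series  # indexed by sample id
    reference_group: str
    genes_used: list[str] = field(default_factory=list)
    genes_dropped: list[str] = field(default_factory=list)  # zero reference SD


def signature_scores(
    es: ExpressionSet,
    sets: GeneSetCollection,
    sheet: SampleSheet,
    reference: str,
) -> dict[str, SignatureScore]:
    """Reference-standardized average Z-score per signature and sample.

    z[g, s] = (x[g, s] - mean_ref(g)) / sd_ref(g) with the unbiased (n-1)
    SD over the reference group; the signature score of a sample is the mean
    z over the set's measured genes. Genes with zero reference SD are
    excluded and recorded. The reference-group mean of every score is 0 by
    construction.
    """
    sheet = sheet.aligned_to(es.sample_ids)
    ref_samples = sheet.samples_in(reference)
    if len(ref_samples) < 2:
        raise ValueError(f"reference group {reference!r} needs >= 2 samples")
    values = es.values
    mu_ref = values[ref_samples].mean(axis=1)
    sd_ref = values[ref_samples].std(axis=1, ddof=1)

    out: dict[str, SignatureScore] = {}
    for name, genes in sets.sets.items():
        measured = [g for g in genes if g in values.index]
        if not measured:
            raise ValueError(f"signature {name!r} shares no genes with the expression set")
        usable = [g for g in measured if sd_ref[g] > 0]
        dropped = [g for g in measured if sd_ref[g] == 0]
        if not usable:
            raise ValueError(f"signature {name!r}: all member genes have zero reference variance")
        z = values.loc[usable].sub(mu_ref[usable], axis=0).div(sd_ref[usable], axis=0)
        out[name] = SignatureScore(name, z.mean(axis=0), reference, usable, dropped)
    return out


def signature_group_test(score: SignatureScore, sheet: SampleSheet) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing the two study groups.

    Exact distribution when the combined sample size is <= 20, normal
    approximation with tie correction otherwise.
    """
    sheet = sheet.aligned_to(list(score.scores.index))
    groups = sheet.groups()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = score.scores[sheet.samples_in(groups[0])].to_numpy()
    b = score.scores[sheet.samples_in(groups[1])].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one sample")
    method = "exact" if len(a) + len(b) <= 20 and len(np.unique(np.r_[a, b])) == len(a) + len(b) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def robust_loess(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    robust_iters: int = 3,
) -> np.ndarray:
    """Robust locally weighted polynomial regression evaluated on a grid.

    Classic LOESS: tricube neighbourhood weights over the nearest
    ceil(span * n) points, local polynomial of the given degree, and
    bisquare robustness reweighting of residuals for ``robust_iters``
    iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    q = max(degree + 1, int(np.ceil(span * n)))
    robust_w = np.ones(n)

    def fit_at(x0: float, rw: np.ndarray) -> float:
        d = np.abs(x - x0)
        h = np.sort(d)[min(q, n) - 1]
        h = max(h, 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3 * rw
        mask = w > 0
        deg = min(degree, max(1, mask.sum() - 1))
        coeffs = np.polyfit(x[mask] - x0, y[mask], deg, w=np.sqrt(w[mask]))
        return float(coeffs[-1])

    for _ in range(robust_iters):
        fitted = np.array([fit_at(xi, robust_w) for xi in x])
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        robust_w = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return np.array([fit_at(g, robust_w) for g in grid])


@dataclass
class TrendSummary:
    signature_name: str
    slope_per_week: float
    pearson_r: float
    p: float
    ga_grid: np.ndarray
    loess_curve: np.ndarray  # anchored: value at `loess_anchor` weeks is 0


def signature_ga_trend(
    score: SignatureScore,
    sheet: SampleSheet,
    within: str | None = None,
    loess_anchor: float = 16.0,
    grid_points: int = 100,
) -> TrendSummary:
    """Linear trend of a signature over gestational age plus anchored LOESS.

    The least-squares slope/correlation/p are computed within the ``within``
    group (all samples when None); the LOESS curve is fit over all samples
    and shifted so its fitted value at ``loess_anchor`` weeks is 0, matching
    the convention of plotting all signatures from a common origin.
    """
    sheet = sheet.aligned_to(list(score.scores.index))
    ga_all = sheet.table["ga_weeks"].to_numpy(dtype=float)
    y_all = score.scores.to_numpy()

    if within is not None:
        members = sheet.table["group"] == within
        ga, y = ga_all[members.to_numpy()], y_all[members.to_numpy()]
    else:
        ga, y = ga_all, y_all
    if len(ga) < 4:
        raise ValueError("need >= 4 samples for the trend fit")
    if np.ptp(ga) == 0:
        raise ValueError("gestational age is constant; trend undefined")

    lin = stats.linregress(ga, y)
    lo = min(loess_anchor, float(ga_all.min()))
    grid = np.linspace(lo, float(ga_all.max()), grid_points)
    curve = robust_loess(ga_all, y_all, grid)
    anchor_val = float(np.interp(loess_anchor, grid, curve))
    return TrendSummary(
        score.signature_name,
        float(lin.slope),
        float(lin.rvalue),
        float(lin.pvalue),
        grid,
        curve - anchor_val,
    )
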