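"""Detection-above-background filtering and unsupervised PCA summary.

Only genes detected above background (detection p < 0.05) in at least 25% of
the samples of either study group are retained for differential expression
and splicing; the cohort is summarized by PCA on the top most-varying genes,
whose first component tracks gestational age in this biofluid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MIDTRIMESTER, ExpressionSet, SampleSheet


def detection_filter(
    es: ExpressionSet,
    sheet: SampleSheet,
    p_thresh: float = 0.05,
    frac: float = 0.25,
) -> list[str]:
    """Genes expressed above background in at least `frac` of either group.

    A gene is kept iff the share of samples with detection p < ``p_thresh``
    is >= ``frac`` (inclusive) in group A or in group B. Input order is
    preserved.
    """
    if es.detection_p is None:
        raise ValueError("detection p-values required for filtering")
    sheet = sheet.aligned_to(es.sample_ids)
    groups = sheet.groups()
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    kept_mask = np.zeros(len(es.feature_ids), dtype=bool)
    for g in groups:
        members = sheet.samples_in(g)
        if not members:
            raise ValueError(f"group {g!r} has no samples")
        share = (es.detection_p[members].to_numpy() < p_thresh).mean(axis=1)
        kept_mask |= share >= frac
    return [fid for fid, keep in zip(es.feature_ids, kept_mask) if keep]


@dataclass
class PCASummary:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    top_genes: list[str]
    r_pc1_ga: float
    r_pc1_ga_mid: float

    @property
    def abs_r_pc1_ga(self) -> float:
        return abs(self.r_pc1_ga)


def pca_ga_summary(
    es: ExpressionSet,
    sheet: SampleSheet,
    top_n: int = 1000,
    n_components: int = 5,
) -> PCASummary:
    """PCA of the top-``top_n`` most-varying genes and its link to gestation.

    Genes are ranked by across-sample variance (ties broken by feature id),
    the matrix is centred per gene (no scaling), and sample scores are the
    projections onto the principal axes. Reports Pearson correlation of PC1
    with gestational age overall and within the midtrimester group, signed
    as computed.
    """
    n_samples = len(es.sample_ids)
    if n_samples < 3:
        raise ValueError("PCA summary requires at least 3 samples")
    if top_n > len(es.feature_ids):
        raise ValueError("top_n exceeds the number of features")
    sheet = sheet.aligned_to(es.sample_ids)

    variances = es.values.var(axis=1, ddof=1)
    order = sorted(es.feature_ids, key=lambda fid: (-variances[fid], fid))
    top_genes = order[:top_n]
    x = es.values.loc[top_genes].to_numpy()  # genes x samples
    xc = (x - x.mean(axis=1, keepdims=True)).T  # samples x genes, centred

    n_components = min(n_components, min(xc.shape))
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    total_var = float(np.sum(s**2))
    var_explained = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    # Deterministic sign: largest-magnitude loading of each score vector positive.
    for j in range(n_components):
        k = int(np.argmax(np.abs(scores[:, j])))
        if scores[k, j] < 0:
            scores[:, j] = -scores[:, j]
    score_df = pd.DataFrame(
        scores, index=es.values.columns, columns=[f"PC{j + 1}" for j in range(n_components)]
    )

    ga = sheet.table["ga_weeks"].to_numpy(dtype=float)
    r_all = _pearson(score_df["PC1"].to_numpy(), ga)
    mid = sheet.table["group"] == MIDTRIMESTER
    r_mid = (
        _pearson(score_df.loc[mid.to_numpy(), "PC1"].to_numpy(), ga[mid.to_numpy()])
        if mid.sum() >= 3
        else float("nan")
    )
    return PCASummary(score_df, var_explained, top_genes, r_all, r_mid)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
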