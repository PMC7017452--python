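"""Exon-usage differential splicing: splicing index, within-gene F-test,
and alternative-splicing event classification.

Exon usage is exon-level log2 expression relative to overall gene abundance
in the same sample; the splicing index (SI) is the covariate-adjusted
between-group difference in average usage. A feature is called
differentially spliced when its BH-adjusted p < 0.05 and |SI| exceeds
2-fold. A complementary within-gene F-test asks whether the exon-level
log2 fold changes differ among the exons of a gene. Significant features
are classified into canonical event types (cassette exon, mutually
exclusive exons, alternative 5'/3' splice sites, intron retention) by rules
over the gene model's transcript structure.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionSet, GeneModel
from .de import DesignMatrix, ModeratedFit, bh_adjust, fit_moderated

EVENT_UNASSIGNED = "unassigned"


def exon_usage(exon_es: ExpressionSet, gene_es: ExpressionSet, model: GeneModel) -> pd.DataFrame:
    """u[e, s] = exon log2 expression minus its gene's log2 abundance."""
    gene_values = gene_es.values
    genes = []
    for fid in exon_es.feature_ids:
        gid = model.gene_of(fid)
        if gid not in gene_values.index:
            raise KeyError(f"exon feature {fid} has no gene-level counterpart {gid}")
        genes.append(gid)
    usage = exon_es.values.to_numpy() - gene_values.loc[genes, exon_es.sample_ids].to_numpy()
    return pd.DataFrame(usage, index=exon_es.values.index, columns=exon_es.values.columns)


def _check_two_group(design: DesignMatrix) -> None:
    col = design.matrix[design.contrast].to_numpy()
    levels = np.unique(col)
    if len(levels) == 2:
        for lev in levels:
            if (col == lev).sum() < 2:
                raise ValueError("each group needs at least 2 samples for the SI test")


def splicing_index_test(usage: pd.DataFrame, design: DesignMatrix) -> pd.DataFrame:
    """Per-feature splicing index with moderated-t p-values and BH q.

    The SI (log2) is the tested contrast's coefficient from the linear model
    fit to usage, i.e. the covariate-adjusted difference in average exon
    usage between groups. q-values are BH-adjusted across all tested
    features genome-wide.
    """
    if not np.all(np.isfinite(usage.to_numpy())):
        raise ValueError("usage matrix must be finite")
    _check_two_group(design)
    fit = fit_moderated(usage, design)
    si_log2 = fit.log2fc.to_numpy()
    si_fold = np.sign(si_log2) * np.power(2.0, np.abs(si_log2))
    return pd.DataFrame(
        {
            "si_log2": si_log2,
            "si_fold": si_fold,
            "p": fit.p.to_numpy(),
            "q": bh_adjust(fit.p.to_numpy()),
        },
        index=usage.index,
    )


def diffsplice_ftest(exon_fit: ModeratedFit, model: GeneModel) -> tuple[pd.DataFrame, list[str]]:
    """Within-gene F-test: do exon log2FCs differ among a gene's exons?

    For a gene with k tested exons, each exon's log2FC beta_e is compared to
    the precision-weighted gene mean; F = sum_e w_e (beta_e - beta_bar)^2 /
    (k - 1) with weights w_e = 1 / (v * s2_post_e), referred to an
    F(k - 1, d0 + d_g) distribution. Genes with a single tested exon are
    untestable and returned separately.
    """
    j = list(exon_fit.design.matrix.columns).index(exon_fit.contrast)
    x = exon_fit.design.matrix.to_numpy(dtype=float)
    v = float(np.linalg.inv(x.T @ x)[j, j])

    by_gene: dict[str, list[str]] = {}
    for fid in exon_fit.p.index:
        by_gene.setdefault(model.gene_of(fid), []).append(fid)

    rows, untestable = [], []
    df2 = min(exon_fit.df_total, 1e9)
    for gid in sorted(by_gene):
        fids = by_gene[gid]
        if len(fids) < 2:
            untestable.append(gid)
            continue
        beta = exon_fit.log2fc.loc[fids].to_numpy()
        w = 1.0 / (v * exon_fit.s2_post.loc[fids].to_numpy())
        beta_bar = float(np.sum(w * beta) / np.sum(w))
        k = len(fids)
        f_stat = float(np.sum(w * (beta - beta_bar) ** 2) / (k - 1))
        p = float(stats.f.sf(f_stat, k - 1, df2))
        rows.append((gid, k, f_stat, p))
    table = pd.DataFrame(rows, columns=["gene_id", "n_exons", "F", "p"]).set_index("gene_id")
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table, untestable


def call_splicing(
    si_table: pd.DataFrame,
    model: GeneModel,
    si_fold_thresh: float = 2.0,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Add gene ids and significance flags to a splicing-index table."""
    out = si_table.copy()
    out["gene_id"] = [model.gene_of(fid) for fid in out.index]
    out["significant"] = (out["q"] < q_thresh) & (out["si_fold"].abs() > si_fold_thresh)
    return out


def _transcript_features(model: GeneModel, gene_id: str) -> dict[str, set[str]]:
    return {tid: set(fids) for tid, fids in model.transcripts_of(gene_id).items()}


def _boundary_event(feat, partner, strand: str) -> str | None:
    """Alt 5'/3' call from a boundary disagreement between overlapping exons."""
    if feat.start == partner.start and feat.end != partner.end:
        varies = "end"
    elif feat.end == partner.end and feat.start != partner.start:
        varies = "start"
    else:
        return None
    # The donor (5') splice site sits at the genomic end of an exon on the
    # '+' strand and at the genomic start on the '-' strand.
    donor_side = "end" if strand == "+" else "start"
    return "alt5" if varies == donor_side else "alt3"


def classify_events(records: pd.DataFrame, model: GeneModel) -> pd.Series:
    """Assign an alternative-splicing event type to each significant feature.

    ``records`` must carry columns ``gene_id``, ``si_log2`` and
    ``significant`` indexed by feature id (the output of
    :func:`call_splicing`). Rules, applied in order:

    1. intron retention — significant intronic feature with positive usage shift;
    2. mutually exclusive — two significant non-overlapping exonic features of
       the gene with opposite SI sign that never co-occur in any transcript;
    3. alt 5'/3' site — significant feature overlapping another transcript
       feature with a disagreeing donor/acceptor boundary, resolved by strand;
    4. cassette — internal exonic feature present in >=1 and absent from >=1
       transcript, with non-significant flanking features;
    5. otherwise unassigned.
    """
    events = pd.Series(EVENT_UNASSIGNED, index=records.index[records["significant"]], dtype=object)
    for fid in events.index:
        if fid not in model.features:
            warnings.warn(f"feature {fid} lacks coordinates; event left unassigned")
            continue
        feat = model.features[fid]
        gid = records.loc[fid, "gene_id"]
        si = float(records.loc[fid, "si_log2"])
        tfeats = _transcript_features(model, gid)

        if feat.kind == "intronic":
            if si > 0:
                events.loc[fid] = "intron_retention"
            continue

        gene_records = records[records["gene_id"] == gid]
        sig_others = [
            model.features[g]
            for g in gene_records.index[gene_records["significant"]]
            if g != fid and g in model.features and model.features[g].kind == "exonic"
        ]
        is_me = any(
            not feat.overlaps(other)
            and np.sign(float(gene_records.loc[other.feature_id, "si_log2"])) == -np.sign(si)
            and not any({fid, other.feature_id} <= fset for fset in tfeats.values())
            for other in sig_others
        )
        if is_me:
            events.loc[fid] = "mutually_exclusive"
            continue

        in_any_transcript = any(fid in fset for fset in tfeats.values())
        alt_call = None
        for other in model.features_of(gid, kind="exonic"):
            if other.feature_id == fid or not feat.overlaps(other):
                continue
            if not any(other.feature_id in fset for fset in tfeats.values()):
                continue
            alt_call = _boundary_event(feat, other, feat.strand)
            if alt_call:
                break
        if alt_call and in_any_transcript:
            events.loc[fid] = alt_call
            continue

        exonic = model.features_of(gid, kind="exonic")
        order = [f.feature_id for f in exonic]
        pos = order.index(fid)
        internal = 0 < pos < len(order) - 1
        absent_somewhere = any(fid not in fset for fset in tfeats.values())
        flanks = [order[pos - 1], order[pos + 1]] if internal else []
        flanks_quiet = all(
            not bool(records.loc[fl, "significant"]) for fl in flanks if fl in records.index
        )
        if internal and in_any_transcript and absent_somewhere and tfeats and flanks_quiet:
            events.loc[fid] = "cassette"
    return events


def splice_summary(
    calls: pd.DataFrame,
    events: pd.Series,
    gene_f: pd.DataFrame,
) -> pd.DataFrame:
    """Per-feature table mirroring the reported splicing output: SI, p, q,
    event type and the gene-level F-test q-value."""
    out = calls.copy()
    out["event_type"] = events.reindex(out.index).fillna(EVENT_UNASSIGNED)
    out.loc[~out["significant"], "event_type"] = EVENT_UNASSIGNED
    out["gene_F_q"] = out["gene_id"].map(gene_f["q"]).to_numpy() if len(gene_f) else np.nan
    return out[["gene_id", "si_log2", "si_fold", "p", "q", "significant", "event_type", "gene_F_q"]]
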