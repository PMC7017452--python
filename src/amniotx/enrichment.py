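"""Over-representation analysis: gene sets, chromosomes, tissue-specific sets.

All enrichment tests are one-sided hypergeometric (equivalent to a one-sided
Fisher's exact test) of a hit list against a gene universe, BH-adjusted
across the sets tested. Tissue-specific gene sets are derived from a linear
expression atlas by the >30-fold-over-median-of-other-tissues rule.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .de import bh_adjust


def hypergeom_test(
    hits: set[str] | list[str], gene_set: set[str] | list[str], universe: set[str] | list[str]
) -> tuple[int, int, float, float]:
    """One-sided over-representation test of `hits` in `gene_set`.

    Returns (overlap count, testable set size, sample odds ratio, p) with
    p = P(X >= count) under Hypergeometric(N=|universe|, K=|set & universe|,
    n=|hits|). The odds ratio is the 2x2 sample estimate ad/bc; a zero
    denominator cell yields inf, a zero numerator cell yields 0.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    gene_set = set(gene_set) & universe
    count = len(hits & gene_set)
    size = len(gene_set)
    n_univ, n_hits = len(universe), len(hits)
    p = float(stats.hypergeom.sf(count - 1, n_univ, size, n_hits))
    a = count
    b = n_hits - count
    c = size - count
    d = n_univ - n_hits - c
    if b * c == 0:
        odds = math.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return count, size, odds, p


def enrich_collection(
    hits: set[str] | list[str],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
    min_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every set in the collection, BH-adjusted.

    Sets whose testable size (after intersecting with the universe) is below
    ``min_size`` are skipped; records are sorted by q then p.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    universe = set(universe)
    rows, skipped = [], []
    for set_name, genes in collection.sets.items():
        count, size, odds, p = hypergeom_test(hits, genes, universe)
        if size < min_size:
            skipped.append(set_name)
            continue
        rows.append((set_name, count, size, odds, p))
    out = pd.DataFrame(rows, columns=["set_name", "count", "size", "odds_ratio", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out = out.sort_values(["q", "p", "set_name"], kind="mergesort").set_index("set_name")
    out.attrs["skipped_sets"] = skipped
    return out


def chromosome_enrichment(
    de_genes: set[str] | list[str],
    gene_chrom: dict[str, str] | pd.Series,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Per-chromosome over-representation of differential genes."""
    gene_chrom = dict(gene_chrom)
    universe = set(universe)
    mapped = {g for g in universe if g in gene_chrom}
    n_unmapped = len(universe) - len(mapped)
    hits = set(de_genes) & mapped
    chroms = sorted({gene_chrom[g] for g in mapped})
    sets = {c: [g for g in mapped if gene_chrom[g] == c] for c in chroms}
    out = enrich_collection(hits, GeneSetCollection("chromosomes", sets), mapped, min_size=1)
    out.attrs["n_unmapped"] = n_unmapped
    return out


def tissue_specific_sets(
    atlas: pd.DataFrame,
    ratio: float = 30.0,
    top_k: int = 20,
) -> tuple[GeneSetCollection, GeneSetCollection, pd.DataFrame]:
    """Tissue-specific gene sets from a linear-scale genes x tissues atlas.

    A gene is specific to tissue t iff its expression there strictly exceeds
    ``ratio`` times the median of its expression over all other tissues; the
    specificity score is that quotient (infinite when the other-tissue
    median is 0 but the tissue value is positive). Returns the full sets,
    the per-tissue top-``top_k`` sets ranked by descending score (ties by
    gene id), and the gene/tissue/score assignment table.
    """
    if atlas.shape[1] < 2:
        raise ValueError("at least two tissues required")
    values = atlas.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("atlas expression must be non-negative")
    tissues = list(atlas.columns)
    rows = []
    for t_idx, tissue in enumerate(tissues):
        others = np.delete(values, t_idx, axis=1)
        med = np.median(others, axis=1)
        own = values[:, t_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(med > 0, own / med, np.where(own > 0, np.inf, 0.0))
        hit = np.where(med > 0, score > ratio, own > 0)
        for gi in np.flatnonzero(hit):
            rows.append((atlas.index[gi], tissue, float(score[gi])))
    table = pd.DataFrame(rows, columns=["gene_id", "tissue", "score"])
    full, top = {}, {}
    for tissue in tissues:
        sub = table[table["tissue"] == tissue].sort_values(
            ["score", "gene_id"], ascending=[False, True], kind="mergesort"
        )
        if len(sub):
            full[tissue] = list(sub["gene_id"])
            top[tissue] = list(sub["gene_id"].head(top_k))
    return (
        GeneSetCollection("tissue_specific", full, source="atlas"),
        GeneSetCollection(f"tissue_top{top_k}", top, source="atlas"),
        table,
    )
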