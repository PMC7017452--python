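"""Core in-memory containers for the amniotic-fluid transcriptome pipeline.

The pipeline operates on summarized log2 expression (exon/probeset level and
gene level), per-feature detection p-values, a gene model linking probesets
to genes and transcripts, a clinical sample sheet, and named gene-set
collections. Everything downstream (filtering, differential expression,
differential splicing, enrichment, signature scoring) consumes these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIDTRIMESTER = "midtrimester"
TERM = "TNL"


@dataclass
class ExpressionSet:
    """A features x samples log2-intensity matrix with optional detection p-values.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, rows indexed by feature id, columns by
        sample id.
    detection_p
        Optional DataFrame of detection (above-background) p-values with the
        same shape and labels as ``values``.
    level
        ``"exon"`` for probeset-level data, ``"gene"`` for transcript-cluster
        level summaries.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.level not in ("exon", "gene"):
            raise ValueError(f"level must be 'exon' or 'gene', got {self.level!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError("detection_p shape mismatch")
            dp = self.detection_p.to_numpy()
            if np.any((dp < 0) | (dp > 1)):
                raise ValueError("detection p-values outside [0, 1]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, keep: list[str]) -> "ExpressionSet":
        dp = self.detection_p.loc[keep] if self.detection_p is not None else None
        return ExpressionSet(self.values.loc[keep], dp, self.level)


@dataclass
class SampleSheet:
    """Per-sample clinical annotation: group, gestational age, covariates.

    ``table`` is indexed by sample id with at least columns ``group`` (one of
    ``midtrimester`` / ``TNL``) and ``ga_weeks``; any further columns are
    treated as covariates (e.g. fetal_sex, parity, smoking, bmi_class,
    collection_mode).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("group", "ga_weeks"):
            if col not in self.table.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        ga = self.table["ga_weeks"].to_numpy(dtype=float)
        if np.any((ga <= 10) | (ga >= 45)):
            raise ValueError("ga_weeks outside plausible range (10, 45)")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample sheet")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def groups(self) -> list[str]:
        return list(pd.unique(self.table["group"]))

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def aligned_to(self, sample_ids: list[str]) -> "SampleSheet":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from sheet: {missing}")
        return SampleSheet(self.table.loc[sample_ids])


@dataclass(frozen=True)
class Feature:
    """A probeset-level feature with genomic coordinates (0-based half-open)."""

    feature_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str = "exonic"  # exonic | intronic | junction

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.feature_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")

    def overlaps(self, other: "Feature") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class GeneModel:
    """Genes -> probeset features -> transcripts (ordered exon lists).

    ``transcripts`` maps transcript id to an ordered list of feature ids; all
    features of a transcript must belong to the same gene.
    """

    features: dict[str, Feature]
    transcripts: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, fids in self.transcripts.items():
            genes = {self.features[f].gene_id for f in fids}
            if len(genes) > 1:
                raise ValueError(f"transcript {tid} spans genes {sorted(genes)}")

    @property
    def gene_ids(self) -> list[str]:
        return sorted({f.gene_id for f in self.features.values()})

    def gene_of(self, feature_id: str) -> str:
        return self.features[feature_id].gene_id

    def features_of(self, gene_id: str, kind: str | None = None) -> list[Feature]:
        feats = [f for f in self.features.values() if f.gene_id == gene_id]
        if kind is not None:
            feats = [f for f in feats if f.kind == kind]
        return sorted(feats, key=lambda f: (f.start, f.end, f.feature_id))

    def transcripts_of(self, gene_id: str) -> dict[str, list[str]]:
        return {
            tid: fids
            for tid, fids in self.transcripts.items()
            if fids and self.features[fids[0]].gene_id == gene_id
        }

    def gene_chrom(self, gene_id: str) -> str:
        for f in self.features.values():
            if f.gene_id == gene_id:
                return f.chrom
        raise KeyError(gene_id)


@dataclass
class GeneSetCollection:
    """Named gene sets (a GMT collection in memory)."""

    name: str
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)
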