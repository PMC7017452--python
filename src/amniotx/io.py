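"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: expression / detection-p TSV (rows = features, columns = samples,
first column = feature id), sample sheet CSV, exon-map TSV (probeset_id,
gene_id, chrom, start, end, strand, kind; 0-based half-open coordinates),
transcripts TSV (transcript_id, gene_id, comma-separated ordered probeset
ids), GMT gene-set files, and genes x tissues atlas TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ExpressionSet, Feature, GeneModel, GeneSetCollection, SampleSheet


def write_expression(es: ExpressionSet, values_path: str | Path, detection_path: str | Path | None = None) -> None:
    es.values.to_csv(values_path, sep="\t", index_label="feature_id")
    if detection_path is not None:
        if es.detection_p is None:
            raise ValueError("ExpressionSet carries no detection p-values")
        es.detection_p.to_csv(detection_path, sep="\t", index_label="feature_id")


def read_expression(
    values_path: str | Path,
    detection_path: str | Path | None = None,
    level: str = "gene",
) -> ExpressionSet:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    detection = pd.read_csv(detection_path, sep="\t", index_col=0) if detection_path else None
    return ExpressionSet(values, detection, level)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index_label="sample_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, index_col="sample_id"))


def write_gene_model(model: GeneModel, exon_map_path: str | Path, transcripts_path: str | Path) -> None:
    rows = [
        (f.feature_id, f.gene_id, f.chrom, f.start, f.end, f.strand, f.kind)
        for f in model.features.values()
    ]
    pd.DataFrame(
        rows, columns=["probeset_id", "gene_id", "chrom", "start", "end", "strand", "kind"]
    ).to_csv(exon_map_path, sep="\t", index=False)
    trows = [
        (tid, model.features[fids[0]].gene_id, ",".join(fids))
        for tid, fids in model.transcripts.items()
    ]
    pd.DataFrame(trows, columns=["transcript_id", "gene_id", "probeset_ids"]).to_csv(
        transcripts_path, sep="\t", index=False
    )


def read_gene_model(exon_map_path: str | Path, transcripts_path: str | Path | None = None) -> GeneModel:
    emap = pd.read_csv(exon_map_path, sep="\t")
    features = {
        r.probeset_id: Feature(
            r.probeset_id, r.gene_id, r.chrom, int(r.start), int(r.end), r.strand,
            getattr(r, "kind", "exonic"),
        )
        for r in emap.itertuples(index=False)
    }
    transcripts: dict[str, list[str]] = {}
    if transcripts_path is not None:
        tdf = pd.read_csv(transcripts_path, sep="\t")
        transcripts = {r.transcript_id: r.probeset_ids.split(",") for r in tdf.itertuples(index=False)}
    return GeneModel(features, transcripts)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_name, genes in collection.sets.items():
            fh.write("\t".join([set_name, collection.source or "na", *genes]) + "\n")


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    source = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = fields[2:]
            source = fields[1]
    return GeneSetCollection(name or Path(path).stem, sets, source)


def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas.to_csv(path, sep="\t", index_label="gene_id")


def read_atlas(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
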