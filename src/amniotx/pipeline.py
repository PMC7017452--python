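"""End-to-end orchestration: filter -> DE -> splicing -> enrichment ->
signatures -> concordance, with run metadata and a reproducible manifest.

A run consumes either a synthetic cohort configuration or file paths to the
plain-text inputs, applies the stage thresholds (detection p < 0.05 in >=25%
of either group; DE q < 0.05 and fold change > 1.25; splicing q < 0.05 and
|SI| > 2-fold; enrichment q < 0.05), and writes one TSV per stage plus a
JSON sidecar recording parameters and seed. The manifest records a sha256
per artifact so end-to-end determinism is checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import enrichment as enr_mod
from . import io as io_mod
from . import preprocess, signatures as sig_mod, splicing as spl_mod
from .concordance import cohort_table, fold_change_concordance
from .containers import MIDTRIMESTER, TERM, ExpressionSet, GeneModel, GeneSetCollection, SampleSheet
from .simulate import CohortConfig, generate_cohort

log = logging.getLogger("amniotx")

STAGES = ("filter", "de", "splice", "enrich", "signatures", "concordance")


@dataclass
class Thresholds:
    detection_p: float = 0.05
    detection_frac: float = 0.25
    de_q: float = 0.05
    de_fc: float = 1.25
    si_q: float = 0.05
    si_fold: float = 2.0
    enrich_q: float = 0.05
    min_set_size: int = 3

    def validate(self) -> None:
        for name in ("detection_p", "detection_frac", "de_q", "si_q", "enrich_q"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.de_fc < 1 or self.si_fold < 1:
            raise ValueError("fold-change thresholds must be >= 1")


@dataclass
class RunConfig:
    """Inputs, thresholds and contrast for one pipeline run."""

    out_dir: str = "amniotx_run"
    seed: int = 0
    synthetic: CohortConfig | None = None
    # file inputs (used when `synthetic` is None)
    exon_values: str | None = None
    exon_detection: str | None = None
    gene_values: str | None = None
    gene_detection: str | None = None
    exon_map: str | None = None
    transcripts: str | None = None
    sample_sheet: str | None = None
    gmt_paths: list[str] = field(default_factory=list)
    atlas_path: str | None = None
    cross_study_path: str | None = None  # TSV: gene_id, log2fc of the other study
    thresholds: Thresholds = field(default_factory=Thresholds)
    contrast_factor: str = "group"
    covariates: list[str] = field(default_factory=lambda: ["fetal_sex"])
    reference_group: str = MIDTRIMESTER
    skip_stages: list[str] = field(default_factory=list)

    def validate(self) -> None:
        self.thresholds.validate()
        unknown = set(self.skip_stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages to skip: {sorted(unknown)}")
        if self.synthetic is None and not (self.gene_values and self.sample_sheet):
            raise ValueError("either a synthetic config or input file paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = CohortConfig(**raw["synthetic"])
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        return cls(**raw)


def validate_inputs(
    gene_es: ExpressionSet,
    sheet: SampleSheet,
    exon_es: ExpressionSet | None = None,
    model: GeneModel | None = None,
    collections: list[GeneSetCollection] = (),
) -> list[dict]:
    """Referential-integrity report; entries have level 'error' or 'warning'."""
    report: list[dict] = []
    missing = [s for s in gene_es.sample_ids if s not in sheet.table.index]
    for s in missing:
        report.append({"level": "error", "message": f"sample {s} missing from sample sheet"})
    if exon_es is not None:
        extra = [s for s in exon_es.sample_ids if s not in gene_es.sample_ids]
        for s in extra:
            report.append({"level": "error", "message": f"exon sample {s} absent from gene-level data"})
        if model is not None:
            for fid in exon_es.feature_ids:
                if fid not in model.features:
                    report.append({"level": "error", "message": f"exon feature {fid} absent from gene model"})
                    break
    if model is not None:
        for tid, fids in model.transcripts.items():
            dangling = [f for f in fids if f not in model.features]
            if dangling:
                report.append(
                    {"level": "error", "message": f"transcript {tid} references unknown features {dangling[:3]}"}
                )
    universe = set(gene_es.feature_ids)
    for coll in collections:
        members = {g for genes in coll.sets.values() for g in genes}
        if members and not members & universe:
            report.append(
                {"level": "warning", "message": f"collection {coll.name!r} shares no gene ids with the data"}
            )
    return report


class _Artifacts:
    """Tracks written outputs so partial results can be removed on failure."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.paths: list[Path] = []

    def write_tsv(self, name: str, df: pd.DataFrame, sidecar: dict) -> Path:
        path = self.out_dir / name
        df.to_csv(path, sep="\t")
        self.paths.append(path)
        side = path.with_suffix(path.suffix + ".json")
        side.write_text(json.dumps(sidecar, indent=2, default=str))
        self.paths.append(side)
        return path

    def cleanup(self) -> None:
        for p in self.paths:
            p.unlink(missing_ok=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        exon_es, gene_es, model, sheet, truth = generate_cohort(cfg)
        return exon_es, gene_es, model, sheet, truth
    gene_es = io_mod.read_expression(config.gene_values, config.gene_detection, level="gene")
    exon_es = (
        io_mod.read_expression(config.exon_values, config.exon_detection, level="exon")
        if config.exon_values
        else None
    )
    model = io_mod.read_gene_model(config.exon_map, config.transcripts) if config.exon_map else None
    sheet = io_mod.read_sample_sheet(config.sample_sheet)
    return exon_es, gene_es, model, sheet, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest of output artifacts."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    art = _Artifacts(out_dir)
    th = config.thresholds
    skip = set(config.skip_stages)
    counts: dict[str, int] = {}
    meta = {"seed": config.seed, "thresholds": dataclasses.asdict(th), "stage_version": "1"}

    try:
        exon_es, gene_es, model, sheet, truth = _load_inputs(config)
        sheet = sheet.aligned_to(gene_es.sample_ids)
        report = validate_inputs(gene_es, sheet, exon_es, model)
        errors = [r for r in report if r["level"] == "error"]
        if errors:
            raise ValueError(f"input validation failed: {errors}")

        if truth is not None:
            truth_df = pd.DataFrame(
                [
                    (t.gene_id, t.effect_kind, t.event_type or "", ",".join(t.affected_feature_ids), t.planted_log2fc_or_si)
                    for t in truth
                ],
                columns=["gene_id", "effect_kind", "event_type", "affected_feature_ids", "planted_effect"],
            ).set_index("gene_id")
            art.write_tsv("truth.tsv", truth_df, meta)

        kept = gene_es.feature_ids
        if "filter" not in skip:
            kept = preprocess.detection_filter(gene_es, sheet, th.detection_p, th.detection_frac)
            art.write_tsv("kept_genes.tsv", pd.DataFrame({"gene_id": kept}).set_index("gene_id"), meta)
            counts["detected_genes"] = len(kept)
            log.info("stage=filter detected=%d of=%d", len(kept), len(gene_es.feature_ids))
        gene_kept = gene_es.subset_features(kept)
        kept_set = set(kept)

        design = de_mod.build_design(
            sheet, [config.contrast_factor, *config.covariates], config.contrast_factor
        )
        de_table = None
        if "de" not in skip:
            fit = de_mod.fit_moderated(gene_kept, design)
            de_table = de_mod.call_de(fit, th.de_fc, th.de_q)
            art.write_tsv("differential_expression.tsv", de_table, meta)
            counts["de_up"] = int(((de_table["significant"]) & (de_table["direction"] == "up")).sum())
            counts["de_down"] = int(((de_table["significant"]) & (de_table["direction"] == "down")).sum())
            log.info("stage=de up=%d down=%d", counts["de_up"], counts["de_down"])

        splice_table = None
        if "splice" not in skip and exon_es is not None and model is not None:
            exon_kept_ids = [f for f in exon_es.feature_ids if model.gene_of(f) in kept_set]
            exon_kept = exon_es.subset_features(exon_kept_ids)
            usage = spl_mod.exon_usage(exon_kept, gene_kept, model)
            si = spl_mod.splicing_index_test(usage, design)
            calls = spl_mod.call_splicing(si, model, th.si_fold, th.si_q)
            exon_fit = de_mod.fit_moderated(exon_kept, design)
            gene_f, untestable = spl_mod.diffsplice_ftest(exon_fit, model)
            events = spl_mod.classify_events(calls, model)
            splice_table = spl_mod.splice_summary(calls, events, gene_f)
            art.write_tsv("differential_splicing.tsv", splice_table, {**meta, "untestable_genes": len(untestable)})
            counts["spliced_features"] = int(splice_table["significant"].sum())
            counts["spliced_genes"] = int(splice_table.loc[splice_table["significant"], "gene_id"].nunique())
            log.info("stage=splice features=%d genes=%d", counts["spliced_features"], counts["spliced_genes"])

        if "enrich" not in skip and de_table is not None and model is not None:
            de_genes = set(de_table.index[de_table["significant"]])
            chrom_map = {f.gene_id: f.chrom for f in model.features.values() if f.gene_id in kept_set}
            chrom = enr_mod.chromosome_enrichment(de_genes, chrom_map, kept_set)
            art.write_tsv("chromosome_enrichment.tsv", chrom, meta)
            counts["enriched_chromosomes"] = int((chrom["q"] < th.enrich_q).sum())
            for gmt in config.gmt_paths:
                coll = io_mod.read_gmt(gmt)
                res = enr_mod.enrich_collection(de_genes, coll, kept_set, th.min_set_size)
                art.write_tsv(f"enrichment_{coll.name}.tsv", res, meta)
            if config.atlas_path:
                atlas = io_mod.read_atlas(config.atlas_path)
                full_sets, _, _ = enr_mod.tissue_specific_sets(atlas)
                if len(full_sets):
                    res = enr_mod.enrich_collection(
                        de_genes, full_sets, kept_set, th.min_set_size
                    )
                    art.write_tsv("enrichment_tissue_specific.tsv", res, meta)
            log.info("stage=enrich chromosomes_significant=%d", counts["enriched_chromosomes"])

        if "signatures" not in skip and config.gmt_paths:
            for gmt in config.gmt_paths:
                coll = io_mod.read_gmt(gmt)
                members = {g for genes in coll.sets.values() for g in genes}
                if not members & set(gene_kept.feature_ids):
                    continue
                scores = sig_mod.signature_scores(gene_kept, coll, sheet, config.reference_group)
                rows = []
                for name, sc in scores.items():
                    p_group = sig_mod.signature_group_test(sc, sheet)
                    trend = sig_mod.signature_ga_trend(sc, sheet, within=config.reference_group)
                    rows.append((name, p_group, trend.slope_per_week, trend.pearson_r, trend.p))
                summary = pd.DataFrame(
                    rows, columns=["signature", "wilcoxon_p", "slope_per_week", "pearson_r", "trend_p"]
                ).set_index("signature")
                art.write_tsv(f"signatures_{coll.name}.tsv", summary, meta)
                score_tab = pd.DataFrame({n: sc.scores for n, sc in scores.items()}).T
                art.write_tsv(f"signature_scores_{coll.name}.tsv", score_tab, meta)

        if "concordance" not in skip:
            art.write_tsv("cohort_table.tsv", cohort_table(sheet.table), meta)
            if config.cross_study_path and de_table is not None:
                other = pd.read_csv(config.cross_study_path, sep="\t", index_col=0)
                shared = de_table.index.intersection(other.index)
                pairs = pd.DataFrame(
                    {"log2fc_a": de_table.loc[shared, "log2fc"], "log2fc_b": other.iloc[:, 0].loc[shared]}
                )
                res = fold_change_concordance(pairs)
                art.write_tsv(
                    "cross_study_concordance.tsv",
                    pd.DataFrame(
                        [dataclasses.asdict(res)], index=pd.Index(["overall"], name="comparison")
                    ),
                    meta,
                )

        manifest = {
            "config": {
                "seed": config.seed,
                "thresholds": dataclasses.asdict(th),
                "contrast": config.contrast_factor,
                "covariates": config.covariates,
                "skipped": sorted(skip),
            },
            "counts": counts,
            "artifacts": {p.name: _sha256(p) for p in art.paths if p.suffix == ".tsv"},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception:
        art.cleanup()
        raise
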