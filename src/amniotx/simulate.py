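"""Synthetic exon-level cohorts, tissue atlases, and signature overlays.

Every downstream stage of the pipeline is exercised against data produced
here, with a machine-readable truth table of the planted effects. The default
cohort mirrors the study design the pipeline targets: a midtrimester group
(n = 30, gestational age 16.4-24.0 weeks) versus a term-not-in-labor group
(n = 68, 37.1-40.9 weeks), ~10% of genes differentially expressed, ~10%
differentially spliced, and ~5% of genes not expressed above background.

The expression model is additive on the log2 scale: per-gene baseline +
per-feature affinity + planted effect + i.i.d. Gaussian noise. Gene-level
values are the per-sample mean of the gene's exonic features. Planted
splicing offsets are re-centred within each gene so that splicing-only genes
carry no gene-level fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MIDTRIMESTER, TERM, ExpressionSet, Feature, GeneModel, GeneSetCollection, SampleSheet

EVENT_TYPES = ("cassette", "mutually_exclusive", "alt5", "alt3", "intron_retention")

#: Chromosomes assigned round-robin so chromosome enrichment has a known null.
CHROMOSOMES = tuple(f"Chr{i}" for i in range(1, 23)) + ("ChrX", "ChrY")

GA_RANGE_MID = (16.4, 24.0)
GA_RANGE_TERM = (37.1, 40.9)


@dataclass
class CohortConfig:
    """Parameters of a synthetic two-group exon-level cohort."""

    n_group_a: int = 30
    n_group_b: int = 68
    n_genes: int = 2000
    exons_per_gene: tuple[int, int] = (4, 8)
    baseline_mu: float = 7.0
    noise_sd: float = 0.5
    frac_de: float = 0.1
    de_log2fc: float = 1.0
    frac_spliced: float = 0.1
    splice_si_log2: float = 1.5
    splice_event_mix: dict[str, float] = field(
        default_factory=lambda: {
            "cassette": 0.69,
            "alt5": 0.19,
            "alt3": 0.10,
            "intron_retention": 0.02,
            "mutually_exclusive": 0.0,
        }
    )
    frac_unexpressed: float = 0.05
    allow_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_group_a <= 0 or self.n_group_b <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.exons_per_gene
        if lo < 4 or hi < lo:
            raise ValueError("exons_per_gene must be a range with lower bound >= 4")
        for name, frac in (
            ("frac_de", self.frac_de),
            ("frac_spliced", self.frac_spliced),
            ("frac_unexpressed", self.frac_unexpressed),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        unknown = set(self.splice_event_mix) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types in mix: {sorted(unknown)}")
        if abs(sum(self.splice_event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("splice_event_mix must sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    """One planted effect: which gene, what kind, which features, how big."""

    gene_id: str
    effect_kind: str  # de_up | de_down | splice
    event_type: str | None
    affected_feature_ids: tuple[str, ...]
    planted_log2fc_or_si: float


def _allocate_counts(total: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of `total` events over the mix."""
    raw = {k: total * v for k, v in mix.items() if v > 0}
    counts = {k: int(np.floor(x)) for k, x in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: (counts[k] - raw[k], k))[:short]:
        counts[k] += 1
    return counts


def _build_gene(
    gene_idx: int, n_exons: int, event: str | None, rng: np.random.Generator
) -> tuple[list[Feature], dict[str, list[str]], list[str]]:
    """Build one gene's features and transcripts; return affected feature ids.

    Exons are 150 bp, spaced 300 bp apart, so the inter-exon gap can host an
    intronic probeset or an extended alternative splice-site exon variant.
    """
    gid = f"G{gene_idx:05d}"
    chrom = CHROMOSOMES[gene_idx % len(CHROMOSOMES)]
    strand = "+" if rng.integers(2) == 0 else "-"
    base = 10_000 * (gene_idx // len(CHROMOSOMES) + 1)
    feats = [
        Feature(f"{gid}_E{i + 1:02d}", gid, chrom, base + 300 * i, base + 300 * i + 150, strand)
        for i in range(n_exons)
    ]
    all_ids = [f.feature_id for f in feats]
    transcripts = {f"{gid}_T1": list(all_ids)}
    affected: list[str] = []

    if event == "cassette":
        j = int(rng.integers(1, n_exons - 1))
        transcripts[f"{gid}_T2"] = [fid for i, fid in enumerate(all_ids) if i != j]
        affected = [all_ids[j]]
    elif event == "mutually_exclusive":
        j = int(rng.integers(1, n_exons - 2))
        transcripts[f"{gid}_T1"] = [fid for i, fid in enumerate(all_ids) if i != j + 1]
        transcripts[f"{gid}_T2"] = [fid for i, fid in enumerate(all_ids) if i != j]
        affected = [all_ids[j], all_ids[j + 1]]
    elif event in ("alt5", "alt3"):
        j = int(rng.integers(1, n_exons - 1))
        ref = feats[j]
        # Donor (5') boundary is the genomic end on '+' strand, start on '-'.
        move_end = (ref.strand == "+") == (event == "alt5")
        if move_end:
            alt = Feature(f"{gid}_E{j + 1:02d}alt", gid, chrom, ref.start, ref.end + 80, strand)
        else:
            alt = Feature(f"{gid}_E{j + 1:02d}alt", gid, chrom, ref.start - 80, ref.end, strand)
        feats.append(alt)
        transcripts[f"{gid}_T2"] = [alt.feature_id if i == j else fid for i, fid in enumerate(all_ids)]
        affected = [alt.feature_id]
    elif event == "intron_retention":
        j = int(rng.integers(0, n_exons - 1))
        intron = Feature(
            f"{gid}_I{j + 1:02d}", gid, chrom, feats[j].end + 10, feats[j + 1].start - 10, strand, "intronic"
        )
        feats.append(intron)
        affected = [intron.feature_id]
    return feats, transcripts, affected


def _sample_sheet(config: CohortConfig, rng: np.random.Generator) -> SampleSheet:
    n_a, n_b = config.n_group_a, config.n_group_b
    ids = [f"MID{i + 1:03d}" for i in range(n_a)] + [f"TNL{i + 1:03d}" for i in range(n_b)]
    ga = np.concatenate(
        [rng.uniform(*GA_RANGE_MID, size=n_a), rng.uniform(*GA_RANGE_TERM, size=n_b)]
    )
    # Covariate frequencies mirror the cohort the pipeline targets: ~27% /
    # ~4% nulliparous, ~13% / ~19% smokers, mostly cesarean collection at term.
    table = pd.DataFrame(
        {
            "group": [MIDTRIMESTER] * n_a + [TERM] * n_b,
            "ga_weeks": np.round(ga, 2),
            "fetal_sex": rng.choice(["male", "female"], size=n_a + n_b, p=[0.5, 0.5]),
            "parity": np.concatenate(
                [
                    rng.choice(["nulliparous", "parous"], size=n_a, p=[0.27, 0.73]),
                    rng.choice(["nulliparous", "parous"], size=n_b, p=[0.05, 0.95]),
                ]
            ),
            "smoking": np.concatenate(
                [
                    rng.choice(["yes", "no"], size=n_a, p=[0.13, 0.87]),
                    rng.choice(["yes", "no"], size=n_b, p=[0.19, 0.81]),
                ]
            ),
            "bmi_class": rng.choice(["lean", "overweight", "obese"], size=n_a + n_b, p=[0.35, 0.25, 0.4]),
            "collection_mode": ["transabdominal"] * n_a
            + list(rng.choice(["cesarean", "transabdominal"], size=n_b, p=[0.94, 0.06])),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return SampleSheet(table)


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionSet, ExpressionSet, GeneModel, SampleSheet, list[TruthRecord]]:
    """Simulate a two-group exon-level cohort with planted DE and splicing.

    Returns the exon-level and gene-level expression sets (both with
    detection p-values), the gene model, the sample sheet, and the truth
    table of planted effects. The same seed always yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sheet = _sample_sheet(config, rng)
    n_samples = config.n_group_a + config.n_group_b
    in_b = np.array([g == TERM for g in sheet.table["group"]])

    n_de = int(round(config.frac_de * config.n_genes))
    n_spliced = int(round(config.frac_spliced * config.n_genes))
    n_unexpr = int(round(config.frac_unexpressed * config.n_genes))
    if not config.allow_overlap and n_de + n_spliced + n_unexpr > config.n_genes:
        raise ValueError("planted fractions exceed the gene universe")

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    perm = rng.permutation(config.n_genes)
    unexpr_idx = set(perm[:n_unexpr].tolist())
    de_idx = set(perm[n_unexpr : n_unexpr + n_de].tolist())
    if config.allow_overlap:
        splice_pool = [i for i in perm[n_unexpr:] if True]
    else:
        splice_pool = perm[n_unexpr + n_de :]
    splice_idx = list(splice_pool[:n_spliced])
    event_counts = _allocate_counts(n_spliced, config.splice_event_mix)
    event_of: dict[int, str] = {}
    cursor = 0
    for ev in EVENT_TYPES:
        for _ in range(event_counts.get(ev, 0)):
            event_of[splice_idx[cursor]] = ev
            cursor += 1

    lo, hi = config.exons_per_gene
    n_exons_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    mu_gene = config.baseline_mu + rng.normal(0.0, 1.0, size=config.n_genes)
    mu_gene[list(unexpr_idx)] = config.baseline_mu - 3.0

    features: dict[str, Feature] = {}
    transcripts: dict[str, list[str]] = {}
    truth: list[TruthRecord] = []
    rows: list[np.ndarray] = []
    feature_order: list[str] = []
    exonic_of_gene: dict[str, list[str]] = {}

    for gi in range(config.n_genes):
        gid = gene_ids[gi]
        event = event_of.get(gi)
        feats, trans, affected = _build_gene(gi, int(n_exons_per_gene[gi]), event, rng)
        transcripts.update(trans)
        exonic_ids = [f.feature_id for f in feats if f.kind == "exonic"]
        exonic_of_gene[gid] = exonic_ids

        sign = 1.0 if rng.integers(2) == 0 else -1.0
        offsets = {f.feature_id: 0.0 for f in feats}
        if gi in de_idx:
            for fid in exonic_ids:
                offsets[fid] = sign * config.de_log2fc
            truth.append(TruthRecord(gid, "de_up" if sign > 0 else "de_down", None,
                                     tuple(exonic_ids), sign * config.de_log2fc))
        elif event is not None:
            s = config.splice_si_log2
            if event == "intron_retention":
                offsets[affected[0]] = s  # retained intron: usage always shifts up
                truth.append(TruthRecord(gid, "splice", event, tuple(affected), s))
            elif event == "mutually_exclusive":
                offsets[affected[0]] = sign * s
                offsets[affected[1]] = -sign * s
                truth.append(TruthRecord(gid, "splice", event, tuple(affected), sign * s))
            else:
                offsets[affected[0]] = sign * s
                truth.append(TruthRecord(gid, "splice", event, tuple(affected), sign * s))
            # Re-centre over exonic features so gene-level log2FC stays 0
            # (splicing without differential expression).
            recentre = np.mean([offsets[fid] for fid in exonic_ids])
            for fid in exonic_ids:
                offsets[fid] -= recentre

        for f in feats:
            features[f.feature_id] = f
            affinity = rng.normal(0.0, 0.25)
            level = mu_gene[gi] + affinity
            if f.kind == "intronic" and offsets[f.feature_id] == 0.0:
                level -= 2.0  # background intronic signal sits below the exons
            row = level + rng.normal(0.0, config.noise_sd, size=n_samples)
            row[in_b] += offsets[f.feature_id]
            rows.append(row)
            feature_order.append(f.feature_id)

    exon_values = pd.DataFrame(np.vstack(rows), index=pd.Index(feature_order, name="feature_id"),
                               columns=sheet.sample_ids)
    gene_values = pd.DataFrame(
        {gid: exon_values.loc[exonic_of_gene[gid]].mean(axis=0) for gid in gene_ids}
    ).T
    gene_values.index.name = "feature_id"
    gene_values.columns = exon_values.columns

    gene_detect = np.empty((config.n_genes, n_samples))
    for gi in range(config.n_genes):
        if gi in unexpr_idx:
            gene_detect[gi] = rng.uniform(0.0, 1.0, size=n_samples)
        else:
            gene_detect[gi] = rng.uniform(0.0, 0.04, size=n_samples)
    gene_dp = pd.DataFrame(gene_detect, index=gene_values.index, columns=gene_values.columns)
    # Exon-level detection mirrors the gene-level call of the parent gene.
    unexpr_gids = {gene_ids[i] for i in unexpr_idx}
    exon_detect = np.empty((len(feature_order), n_samples))
    for i, fid in enumerate(feature_order):
        if features[fid].gene_id in unexpr_gids:
            exon_detect[i] = rng.uniform(0.0, 1.0, size=n_samples)
        else:
            exon_detect[i] = rng.uniform(0.0, 0.04, size=n_samples)
    exon_dp = pd.DataFrame(exon_detect, index=exon_values.index, columns=exon_values.columns)

    exon_es = ExpressionSet(exon_values, exon_dp, level="exon")
    gene_es = ExpressionSet(gene_values, gene_dp, level="gene")
    model = GeneModel(features, transcripts)
    return exon_es, gene_es, model, sheet, truth


def generate_atlas(
    n_tissues: int,
    n_genes: int,
    n_specific_per_tissue: int,
    specificity_ratio: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Simulate a linear-scale genes x tissues atlas with planted specific genes.

    Each planted gene's expression in its target tissue is set to exactly
    ``specificity_ratio`` times the median of its values in the other
    tissues, so a downstream >r rule recovers it iff specificity_ratio > r.
    Background genes are flat across tissues up to multiplicative noise.
    """
    if specificity_ratio <= 1:
        raise ValueError("specificity_ratio must exceed 1")
    if n_specific_per_tissue * n_tissues > n_genes:
        raise ValueError("more planted specific genes than genes in the atlas")
    rng = np.random.default_rng(seed)
    tissues = [f"tissue_{t + 1:02d}" for t in range(n_tissues)]
    gene_ids = [f"AG{i:05d}" for i in range(n_genes)]
    values = 10.0 * np.exp(rng.normal(0.0, 0.1, size=(n_genes, n_tissues)))
    truth: dict[str, list[str]] = {t: [] for t in tissues}
    gi = 0
    for t_idx, tissue in enumerate(tissues):
        for _ in range(n_specific_per_tissue):
            others = np.delete(values[gi], t_idx)
            med = float(np.median(others))
            v = specificity_ratio * med
            while v / med > specificity_ratio:  # guard float round-up past the ratio
                v = np.nextafter(v, 0.0)
            values[gi, t_idx] = v
            truth[tissue].append(gene_ids[gi])
            gi += 1
    atlas = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=tissues)
    return atlas, truth


_TRAJECTORIES = ("monotone_up", "monotone_down", "peak_mid")


def _trajectory_shape(name: str, ga: np.ndarray) -> np.ndarray:
    """Unit-amplitude trajectory over gestational age (weeks).

    monotone shapes are flat (0) across the midtrimester window and reach
    magnitude 1 at the median term gestational age (39 weeks), so the
    reference-group standardization downstream is not distorted; peak_mid
    rises and falls with its maximum strictly inside the observed GA range.
    """
    if name == "monotone_up":
        return np.clip((ga - GA_RANGE_MID[1]) / (39.0 - GA_RANGE_MID[1]), 0.0, None)
    if name == "monotone_down":
        return -np.clip((ga - GA_RANGE_MID[1]) / (39.0 - GA_RANGE_MID[1]), 0.0, None)
    if name == "peak_mid":
        return np.sin(np.pi * np.clip((ga - 16.0) / 25.0, 0.0, 1.0))
    raise ValueError(f"unknown trajectory {name!r}; expected one of {_TRAJECTORIES}")


def generate_signatures(
    gene_es: ExpressionSet,
    sheet: SampleSheet,
    cell_types: list[str],
    genes_per_set: int = 3,
    trajectory: str | dict[str, str] = "monotone_up",
    effect_sd: float = 1.8,
    seed: int = 0,
    exclude: tuple[str, ...] = (),
) -> tuple[GeneSetCollection, ExpressionSet, dict[str, dict]]:
    """Overlay cell-type signature trajectories on an existing cohort.

    Member genes are drawn from the cohort (disjoint from ``exclude``, e.g.
    planted DE/splice genes) and shifted along gestational age by
    ``effect_sd`` reference-group standard deviations times the unit
    trajectory shape. Returns the signature collection, the modified
    gene-level expression set, and the truth trajectories.
    """
    rng = np.random.default_rng(seed)
    traj_of = {ct: trajectory for ct in cell_types} if isinstance(trajectory, str) else dict(trajectory)
    for ct in cell_types:
        _trajectory_shape(traj_of[ct], np.array([20.0]))  # validate names early
    pool = [g for g in gene_es.feature_ids if g not in set(exclude)]
    needed = genes_per_set * len(cell_types)
    if needed > len(pool):
        raise ValueError("not enough unplanted genes for the requested signatures")
    chosen = rng.choice(len(pool), size=needed, replace=False)

    sheet = sheet.aligned_to(gene_es.sample_ids)
    ga = sheet.table["ga_weeks"].to_numpy(dtype=float)
    ref_samples = sheet.samples_in(MIDTRIMESTER)
    values = gene_es.values.copy()
    sets: dict[str, list[str]] = {}
    truth: dict[str, dict] = {}
    for k, ct in enumerate(cell_types):
        members = [pool[i] for i in chosen[k * genes_per_set : (k + 1) * genes_per_set]]
        shape = _trajectory_shape(traj_of[ct], ga)
        for g in members:
            sigma_ref = float(values.loc[g, ref_samples].std(ddof=1))
            values.loc[g] = values.loc[g].to_numpy() + effect_sd * sigma_ref * shape
        sets[ct] = members
        truth[ct] = {"trajectory": traj_of[ct], "amplitude": effect_sd, "genes": members}
    collection = GeneSetCollection("synthetic_single_cell", sets, source="synthetic")
    return collection, ExpressionSet(values, gene_es.detection_p, gene_es.level), truth
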