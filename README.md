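# amniotx

Exon-resolution analysis of the amniotic-fluid (AF) cell-free transcriptome.

Cell-free RNA in amniotic fluid reflects fetal development and placental
cellular dynamics: as gestation advances from the midtrimester to term, a
large fraction of detected genes change in expression, and even more change
in how their exons are used. `amniotx` is a Python library for obstetric
transcriptomics researchers that implements the full analysis chain for such
cohorts — from summarized log2 expression matrices down to enrichment tables
and cell-type signature trajectories — together with a synthetic-cohort
generator that plants known effects so every stage can be benchmarked
against ground truth.

## What it computes

**Detection filtering.** A gene is retained when detected above background
(detection *p* < 0.05) in at least 25% of the samples of either study group
(midtrimester or term-not-in-labor, TNL).

**Differential expression.** Per-gene linear models with covariate
adjustment and an empirical-Bayes moderated *t*-test. Residual variances
s²_g are shrunk toward a prior estimated by the method of moments on
log s²_g:

    s̃²_g = (d₀s₀² + d_g s²_g) / (d₀ + d_g),    t_g = β̂_g / (s̃_g √v)

with *t_g* referred to a *t* distribution on d₀ + d_g degrees of freedom.
Genes are called at BH *q* < 0.05 with fold change > 1.25.

**Differential splicing.** Exon usage is exon-level log2 expression relative
to overall gene abundance in the same sample, u_{e,s} = x_{e,s} − g_{G(e),s}.
The splicing index (SI) is the covariate-adjusted between-group difference
in average usage; probesets are called at *q* < 0.05 and |SI| > 2-fold. A
within-gene F-test (do exon log2 fold changes differ among a gene's exons?)
corroborates the calls, and significant probesets are classified into
cassette exon, mutually exclusive exons, alternative 5′/3′ splice site, or
intron retention using rules over the transcript structure of the gene model.

**Enrichment.** One-sided hypergeometric over-representation of hit lists in
gene-set collections (GMT), per chromosome, and in tissue-specific sets
derived from an expression atlas by the >30×-median-of-other-tissues rule.

**Signature tracking.** Per-gene Z-scores standardized against the reference
group (mean and SD from midtrimester samples), averaged over the genes of a
cell-type or tissue signature so each gene contributes equally; compared
between groups by Wilcoxon rank-sum and tracked over gestational age with a
robust locally-quadratic LOESS curve anchored at 16 weeks.

**Concordance.** Cross-study comparison of log2 fold changes by Spearman
correlation and direction-of-change agreement, plus cohort demographic
tables (Welch *t* / Fisher exact).

## Worked example

```python
from amniotx import (CohortConfig, build_design, call_de, detection_filter,
                     fit_moderated, generate_cohort)

exon_es, gene_es, model, sheet, truth = generate_cohort(CohortConfig(n_genes=600, seed=3))
design = build_design(sheet, ["group", "fetal_sex"], "group")
fit = fit_moderated(gene_es, design)
table = call_de(fit, fc_thresh=1.25, q_thresh=0.05)
```

Running `python examples/03_differential_expression.py` (the same analysis)
prints:

```
empirical-Bayes prior: d0 = 32.7 extra df, s0^2 = 0.0415
significant: 26 up, 34 down (q<0.05, FC>1.25)
sensitivity vs planted truth: 1.00
observed FDR: 0.000
```

`d0` is the information each gene borrows from the ensemble (about 33
pseudo-observations of variance here), `s0²` the prior residual variance;
all 50 planted ±1 log2FC genes are recovered with no false calls at the
configured noise level. The other scripts in `examples/` walk through one
capability each — simulation, filtering/PCA, splicing, enrichment,
signatures, concordance, and the end-to-end pipeline — and print a line
explaining each number they produce.

A thin CLI mirrors the stages for shell use:

```bash
amniotx simulate --seed 4 --n-genes 500 --out cohort/
amniotx de --expression cohort/gene_expression.tsv --sample-sheet cohort/sample_sheet.csv --out de.tsv
amniotx run-all --config run.yaml
```

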