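"""Simulate a two-group amniotic-fluid cohort with planted ground truth.

Generates exon- and gene-level log2 expression for a midtrimester (n=30) vs
term (n=68) design, with 10% of genes differentially expressed, 10%
differentially spliced, and 5% unexpressed, then prints what was planted.
"""

from collections import Counter

from amniotx import CohortConfig, generate_cohort

cfg = CohortConfig(n_genes=500, seed=1)
exon_es, gene_es, model, sheet, truth = generate_cohort(cfg)

print(f"exon matrix: {exon_es.values.shape[0]} probesets x {exon_es.values.shape[1]} samples")
print(f"gene matrix: {gene_es.values.shape[0]} genes")
print(f"groups: {dict(sheet.table['group'].value_counts())}")
print(f"planted effects: {Counter((t.effect_kind, t.event_type) for t in truth)}")
# Each TruthRecord names the gene, the effect kind (de_up/de_down/splice),
# the affected probesets, and the signed log2 effect size — the ground truth
# every downstream stage is benchmarked against.
t = truth[0]
print(f"example: {t.gene_id} {t.effect_kind} effect={t.planted_log2fc_or_si:+.2f} "
      f"features={t.affected_feature_ids[:2]}...")
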