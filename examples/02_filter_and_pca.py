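"""Detection filtering and the PCA view of gestational age.

Keeps genes detected above background (p < 0.05) in at least 25% of the
samples of either group, then summarizes the cohort by PCA of the top
most-varying genes. PC1 tracks gestational age because the term/midtrimester
contrast dominates the transcriptome.
"""

from amniotx import CohortConfig, detection_filter, generate_cohort, pca_ga_summary

_, gene_es, _, sheet, _ = generate_cohort(CohortConfig(n_genes=800, seed=2))

kept = detection_filter(gene_es, sheet, p_thresh=0.05, frac=0.25)
print(f"detected above background: {len(kept)}/{len(gene_es.feature_ids)} genes "
      f"({100 * len(kept) / len(gene_es.feature_ids):.0f}%)")

res = pca_ga_summary(gene_es.subset_features(kept), sheet, top_n=500)
print(f"variance explained by PC1: {100 * res.variance_explained[0]:.1f}%")
print(f"correlation of PC1 with gestational age: |R| = {abs(res.r_pc1_ga):.3f}")
# A high |R| means the leading axis of expression variation is the
# midtrimester-to-term developmental trajectory, not technical noise.
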