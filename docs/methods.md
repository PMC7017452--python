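# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the limitations of `amniotx`.

## Study design the package targets

A two-group cross-sectional design over gestational age (GA): a
midtrimester group sampled at 16.4–24.0 weeks and a term-not-in-labor (TNL)
group at 37.1–40.9 weeks, with defaults n = 30 and n = 68. Expression is
consumed as summarized log2 intensities at two resolutions: probeset level
(exons, exon–exon junctions, intronic probes) and gene level (one value per
transcript cluster), plus per-feature detection p-values. Upstream
background correction/normalization/summarization (RMA-style) is out of
scope; the pipeline starts at the summarized matrices.

## Detection filter

A gene is retained iff the share of samples with detection p < `p_thresh`
(default 0.05) is ≥ `frac` (default 0.25) in *either* group. The boundary is
inclusive: 1 detected of 4 samples (exactly 25%) keeps the gene. The filter
is applied at gene level; exon-level features inherit the decision of their
parent gene. The filter is monotone in both thresholds (property-tested).

## Differential expression: the moderated t

Each gene's log2 expression is fit by OLS against a shared design matrix
(intercept + treatment-coded factors + untransformed continuous
covariates). The group factor uses `midtrimester` as the reference level
whenever present, so the tested coefficient is the term-vs-midtrimester
log2 fold change; other categorical factors use the first sorted level, and
any reference can be overridden (`build_design(reference=...)`). Rank
deficiency (e.g. collection mode nested in group) is rejected at
construction.

The empirical-Bayes prior (d₀, s₀²) is estimated by the method of moments
on z = log s²_g, matching the scaled log-χ² distribution that s²_g follows
under the hierarchical model:

- e_g = z_g − ψ(d/2) + log(d/2), with d the residual df;
- var(e) − ψ′(d/2) > 0 identifies d₀ via 2·ψ′⁻¹(·) (trigamma inversion by
  Newton on the reciprocal); otherwise d₀ = ∞ (no variance heterogeneity);
- s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).

Then s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), t_g = β̂_g/(s̃_g√v) with v the
contrast's unscaled variance, and p two-sided from t(d₀ + d). The estimator
recovers known (d₀, s₀²) on simulated variances within sampling error
(unit-tested) and collapses to the ordinary per-gene t when d₀ is forced to
0 — that equivalence against the pooled-variance two-sample t is an oracle
test. Features with zero residual variance borrow the smallest positive
observed s² so no t statistic is infinite; if *every* feature has zero
residual variance the moment estimation is undefined and an error is
raised.

Calls require both BH q < 0.05 and |log2FC| > log2(1.25) ≈ 0.322. BH is the
canonical step-up (cumulative minimum from the largest rank), delegated to
statsmodels and verified against a hand-written oracle. Note that BH is not
idempotent in general (BH([0.5, 1]) = [1, 1]), so no such property is
claimed.

Covariate selection mirrors the "adjust only for covariates with a
significant effect" idea: `select_covariates` includes a candidate iff its
own single-factor contrast yields at least one feature at q < 0.05. The
pipeline default adjusts the group contrast for fetal sex.

## Differential splicing

Exon usage u_{e,s} = x_{e,s} − g_{G(e),s} (log2). The splicing index is the
tested coefficient of the same moderated-t machinery applied to usage; its
signed linear fold is sign(SI)·2^|SI|. "SI > 2-fold" is read as |signed
fold| > 2, i.e. |SI log2| > 1. BH for exon tests is applied genome-wide
across all tested features (the simplest defensible family; recorded in
output metadata).

The within-gene F-test compares each gene's exon log2FCs β_e to their
precision-weighted mean (weights 1/(v·s̃²_e)): F = Σ w_e(β_e − β̄)²/(k−1),
referred to F(k−1, d₀+d). Genes with one tested exon are untestable and
reported separately. Uniform gene-wide expression shifts cancel exactly in
usage, so DE-only genes show SI ≈ 0 and F ≈ 0 — the separability of
"differential splicing without expression" is tested on planted truth.

Event classification is a documented rule set over the gene model (the
vendor event-estimation algorithm is proprietary and is *not* reproduced;
labels are validated only against planted synthetic truth). Rules in order,
for each significant probeset:

1. **intron retention** — intronic-region probeset with positive usage shift;
2. **mutually exclusive** — two significant, non-overlapping exonic
   probesets of the gene with opposite SI signs that co-occur in no
   transcript;
3. **alt 5′/3′ site** — the probeset overlaps another transcript-member
   exon whose donor/acceptor boundary disagrees; a variable genomic *end* is
   a donor (5′) variant on the + strand and an acceptor (3′) variant on the
   − strand (labels swap under strand reversal; tested);
4. **cassette** — internal exonic probeset present in ≥1 and absent from ≥1
   transcript, with non-significant flanking probesets;
5. otherwise **unassigned**.

## Enrichment

One-sided over-representation p = P(X ≥ overlap) under
Hypergeometric(N = |universe|, K = |set ∩ universe|, n = |hits|), equivalent
to a one-sided Fisher test; the odds ratio is the 2×2 sample estimate
(zero cells yield 0 or ∞, documented). Sets smaller than `min_size` = 3
after universe intersection are skipped and logged. The universe defaults
to detected genes and is caller-configurable. The tissue rule assigns gene
g to tissue t iff expr(g,t) > 30 × median of its expression in the other
tissues (strict inequality; a zero other-tissue median assigns the gene iff
its own value is positive, with infinite score).

## Signatures

z_{g,s} = (x_{g,s} − μ_g^ref)/σ_g^ref with the unbiased (n−1) SD over the
reference group; a signature score is the mean z over the set's measured
genes, so the reference-group mean of every score is exactly 0 and each
gene contributes equally regardless of dynamic range (doubling one gene's
scale leaves the score unchanged — tested). Genes with zero reference SD
are excluded and recorded. Group comparison uses the Wilcoxon rank-sum
test: exact distribution when the combined n ≤ 20 without ties, normal
approximation with tie correction otherwise (two-sided by default; the
sidedness convention is a deliberate default, not a claim about any
particular dataset).

GA trends: least-squares slope/correlation within the chosen group, plus a
LOESS curve over all samples shifted so its value at 16 weeks is 0 (common
origin for plotting several signatures). The LOESS is the classic robust
locally weighted regression — tricube neighbourhood weights over
ceil(span·n) nearest points, local polynomial fit, bisquare robustness
reweighting — with span 0.75, degree 2, and 3 robustness iterations as
defaults. It is implemented in-package because the installed Python stack
offers only degree-1 lowess; the implementation is validated on smooth
signals and gross-outlier robustness.

## Concordance and cohort statistics

Spearman correlation uses average ranks for ties; direction agreement is
the share of sign matches among pairs where both fold changes are non-zero
(zero-FC pairs are excluded from the denominator and counted). Fisher's
exact 2×2 test is two-sided by the point-probability convention (sum of
table probabilities ≤ the observed one), which reproduces standard
software; a zero margin returns p = 1 with a warning. Welch's t uses the
Welch–Satterthwaite df; two zero-variance samples give p = 1 (equal means)
or p = 0 with a warning (unequal).

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed, not a calibration dial; its
defaults are the targeted study conditions.

- **Cohort:** n = 30/68; GA uniform on [16.4, 24.0] and [37.1, 40.9] weeks;
  covariates (fetal sex, parity, smoking, BMI class, collection mode) drawn
  with frequencies mirroring the targeted cohort (e.g. ~27% vs ~4%
  nulliparous; all-transabdominal midtrimester vs 94% cesarean term
  collection, which deliberately makes collection mode nearly confounded
  with group).
- **Expression model:** x_{e,s} = μ_g + a_e + effect + ε, ε ~ N(0, σ²)
  i.i.d. on the log2 scale, μ_g ~ N(7, 1), exon affinity a_e ~ N(0, 0.25²).
  The Gaussian noise model matches the behaviour of RMA-summarized
  intensities and keeps closed-form power checks; σ (default 0.5) is a
  parameter, not an empirical estimate. Gene-level values are the
  per-sample mean of the gene's exonic probesets (consistent with the
  usage definition; intronic probesets are excluded and sit 2 log2 units
  below the exons unless an intron-retention effect is planted).
- **Planted effects:** 10% DE genes (all exons shifted ±1 log2 in the term
  group), 10% spliced genes (affected exons shifted ±1.5 log2, offsets
  re-centred within the gene so the gene-level fold change is exactly 0 —
  note this attenuates the realized per-exon usage shift by a factor
  (1 − 1/k) for a k-exon gene), 5% unexpressed genes. The event-type mix
  defaults to the classified proportions the targeted study reports
  (cassette 69%, alt5 19%, alt3 10%, intron retention 2%); each event type
  is planted with a transcript structure that its classification rule can
  recover. Detection p-values are Uniform(0, 0.04) for expressed and
  Uniform(0, 1) for unexpressed genes — this reproduces the filter's
  behaviour without modelling background probes.
- **Chromosomes** are assigned round-robin Chr1..Chr22, X, Y so chromosome
  enrichment has a known null.
- **Atlas:** background genes flat across tissues up to 10% multiplicative
  noise; planted specific genes sit at exactly `specificity_ratio` times
  the median of their other-tissue values (guarded against floating-point
  round-up so a boundary gene never leaks past a strict > rule).
- **Signature overlays** add effect_sd · σ_g^ref · shape(GA) to member
  genes: monotone shapes are 0 across the midtrimester window and reach
  magnitude 1 at the median term GA (39 weeks), so the reference
  standardization is undistorted and the planted amplitude reads back
  directly; `peak_mid` is a half-sine over 16–41 weeks peaking near 28.5
  weeks.

What the generator does **not** emulate: probe-level intensities, batch
effects, RNA degradation, correlated noise between exons beyond the shared
gene mean, heavy-tailed intensity distributions, and realistic annotation
complexity (overlapping genes, many-transcript loci). Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated model, not performance on real arrays.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 300–2000 genes (≈2k–12k probesets ×
98 samples), sizes chosen so the full suite and the acceptance script each
run in seconds while leaving Monte-Carlo margins comfortably inside the
asserted tolerances. All randomness flows through `numpy.random.default_rng`
seeded from configuration; identical seeds give bit-identical matrices,
truth tables, and pipeline manifests (checksummed).

## Known limitations

- The moment-based prior assumes a common residual df across features
  (true here, where one design is fit to all features).
- The event classifier assigns one label per significant probeset
  independently; composite events spanning several probesets are reported
  probeset-wise.
- The SI test inherits the moderated-t normality assumptions on usage;
  usage values within a gene are weakly negatively correlated through the
  shared gene mean, which the genome-wide BH family ignores (calibration is
  nonetheless verified empirically on null cohorts).
- LOESS anchoring extrapolates to 16 weeks when no sample is that young;
  with the default GA windows the youngest samples are at 16.4 weeks, so
  the extrapolation is short.
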