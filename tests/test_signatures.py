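"""Reference-group Z-score signatures: scoring, group tests, GA trends."""

import itertools

import numpy as np
import pandas as pd
import pytest

import amniotx as ax
from amniotx.containers import MIDTRIMESTER, TERM, ExpressionSet, GeneSetCollection, SampleSheet
from amniotx.signatures import robust_loess


def _cohort_with_sets(seed=0, n_genes=40, n_a=6, n_b=8):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n_a + n_b)]
    values = pd.DataFrame(
        rng.normal(7, 1, (n_genes, n_a + n_b)), index=[f"g{i}" for i in range(n_genes)], columns=samples
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": [MIDTRIMESTER] * n_a + [TERM] * n_b,
                "ga_weeks": np.r_[rng.uniform(16.4, 24, n_a), rng.uniform(37.1, 40.9, n_b)],
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return ExpressionSet(values), sheet


class TestScores:
    def test_reference_group_mean_is_exactly_zero(self):
        es, sheet = _cohort_with_sets()
        coll = GeneSetCollection("c", {"sig": [f"g{i}" for i in range(5)]})
        sc = ax.signature_scores(es, coll, sheet, MIDTRIMESTER)["sig"]
        ref = sheet.samples_in(MIDTRIMESTER)
        assert sc.scores[ref].mean() == pytest.approx(0.0, abs=1e-12)

    def test_single_gene_set_score_equals_that_genes_z(self):
        es, sheet = _cohort_with_sets()
        coll = GeneSetCollection("c", {"solo": ["g3"]})
        sc = ax.signature_scores(es, coll, sheet, MIDTRIMESTER)["solo"]
        ref = sheet.samples_in(MIDTRIMESTER)
        mu = es.values.loc["g3", ref].mean()
        sd = es.values.loc["g3", ref].std(ddof=1)
        assert np.allclose(sc.scores.to_numpy(), ((es.values.loc["g3"] - mu) / sd).to_numpy())

    def test_zero_reference_variance_genes_dropped(self):
        es, sheet = _cohort_with_sets()
        ref = sheet.samples_in(MIDTRIMESTER)
        values = es.values.copy()
        values.loc["g0", ref] = 5.0  # flat in the reference group
        coll = GeneSetCollection("c", {"sig": ["g0", "g1", "g2"]})
        sc = ax.signature_scores(ExpressionSet(values), coll, sheet, MIDTRIMESTER)["sig"]
        assert sc.genes_dropped == ["g0"]
        assert set(sc.genes_used) == {"g1", "g2"}

    def test_standardization_weighs_genes_equally(self):
        """Doubling one gene's scale does not change the score (unlike plain averaging)."""
        es, sheet = _cohort_with_sets()
        coll = GeneSetCollection("c", {"sig": ["g1", "g2"]})
        base = ax.signature_scores(es, coll, sheet, MIDTRIMESTER)["sig"].scores
        values = es.values.copy()
        values.loc["g1"] = values.loc["g1"] * 2  # per-gene affine rescale
        rescaled = ax.signature_scores(ExpressionSet(values), coll, sheet, MIDTRIMESTER)["sig"].scores
        assert np.allclose(base.to_numpy(), rescaled.to_numpy())

    def test_disjoint_membership_rejected(self):
        es, sheet = _cohort_with_sets()
        coll = GeneSetCollection("c", {"sig": ["absent1", "absent2"]})
        with pytest.raises(ValueError, match="no genes"):
            ax.signature_scores(es, coll, sheet, MIDTRIMESTER)

    def test_planted_amplitude_recovered(self, small_cohort):
        """A +1.8 SD monotone overlay is read back as ~1.8 in the term group."""
        _, gene_es, _, sheet, truth = small_cohort
        planted = tuple(t.gene_id for t in truth)
        coll, overlay, _ = ax.generate_signatures(
            gene_es, sheet, ["cyto"], genes_per_set=3, trajectory="monotone_up",
            effect_sd=1.8, seed=6, exclude=planted,
        )
        sc = ax.signature_scores(overlay, coll, sheet, MIDTRIMESTER)["cyto"]
        term_mean = sc.scores[sheet.samples_in(TERM)].mean()
        assert term_mean == pytest.approx(1.8, abs=0.2)


class TestGroupTest:
    def test_exact_enumeration_small_samples(self):
        """{1,2,3} vs {4,5,6}: 2/20 orderings as extreme -> two-sided p = 0.1."""
        samples = [f"S{i}" for i in range(6)]
        sheet = SampleSheet(
            pd.DataFrame(
                {"group": [MIDTRIMESTER] * 3 + [TERM] * 3, "ga_weeks": [20.0] * 3 + [39.0] * 3},
                index=pd.Index(samples, name="sample_id"),
            )
        )
        from amniotx.signatures import SignatureScore

        sc = SignatureScore("s", pd.Series([1, 2, 3, 4, 5, 6], index=samples, dtype=float), MIDTRIMESTER)
        assert ax.signature_group_test(sc, sheet) == pytest.approx(0.1)

    def test_label_swap_symmetry(self, small_cohort):
        _, gene_es, _, sheet, _ = small_cohort
        coll = GeneSetCollection("c", {"sig": gene_es.feature_ids[:4]})
        sc = ax.signature_scores(gene_es, coll, sheet, MIDTRIMESTER)["sig"]
        p1 = ax.signature_group_test(sc, sheet)
        swapped = sheet.table.copy()
        swapped["group"] = swapped["group"].map({MIDTRIMESTER: TERM, TERM: MIDTRIMESTER})
        p2 = ax.signature_group_test(sc, SampleSheet(swapped))
        assert p1 == pytest.approx(p2)

    def test_null_overlay_is_not_significant_more_than_nominal(self, small_cohort):
        _, gene_es, _, sheet, truth = small_cohort
        planted = tuple(t.gene_id for t in truth)
        coll, overlay, _ = ax.generate_signatures(
            gene_es, sheet, [f"null{i}" for i in range(10)], genes_per_set=3,
            trajectory="monotone_up", effect_sd=0.0, seed=8, exclude=planted,
        )
        scores = ax.signature_scores(overlay, coll, sheet, MIDTRIMESTER)
        pvals = [ax.signature_group_test(sc, sheet) for sc in scores.values()]
        assert sum(p < 0.05 for p in pvals) <= 3  # ~nominal false-positive behaviour


class TestTrend:
    def test_score_equal_to_ga_gives_unit_slope(self):
        es, sheet = _cohort_with_sets()
        from amniotx.signatures import SignatureScore

        sc = SignatureScore("s", pd.Series(sheet.table["ga_weeks"].to_numpy(), index=sheet.sample_ids), MIDTRIMESTER)
        trend = ax.signature_ga_trend(sc, sheet)
        assert trend.slope_per_week == pytest.approx(1.0)
        assert trend.pearson_r == pytest.approx(1.0)

    def test_constant_ga_rejected(self):
        es, sheet = _cohort_with_sets()
        from amniotx.signatures import SignatureScore

        table = sheet.table.copy()
        table["ga_weeks"] = 20.0
        sc = SignatureScore("s", pd.Series(np.arange(len(table), dtype=float), index=table.index), MIDTRIMESTER)
        with pytest.raises(ValueError, match="constant"):
            ax.signature_ga_trend(sc, SampleSheet(table))

    def test_peak_mid_trajectory_has_interior_loess_maximum(self, small_cohort):
        _, gene_es, _, sheet, truth = small_cohort
        planted = tuple(t.gene_id for t in truth)
        coll, overlay, _ = ax.generate_signatures(
            gene_es, sheet, ["hof"], genes_per_set=3, trajectory="peak_mid",
            effect_sd=2.0, seed=9, exclude=planted,
        )
        sc = ax.signature_scores(overlay, coll, sheet, MIDTRIMESTER)["hof"]
        trend = ax.signature_ga_trend(sc, sheet)
        peak_ga = trend.ga_grid[np.argmax(trend.loess_curve)]
        assert trend.ga_grid[0] < peak_ga < trend.ga_grid[-1]
        # anchored at 16 weeks
        assert np.interp(16.0, trend.ga_grid, trend.loess_curve) == pytest.approx(0.0, abs=1e-9)

    def test_loess_reproduces_smooth_signal(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 120)
        y = np.sin(x) + rng.normal(0, 0.1, 120)
        grid = np.linspace(0.5, 9.5, 40)
        fit = robust_loess(x, y, grid, span=0.3)
        assert np.max(np.abs(fit - np.sin(grid))) < 0.15

    def test_loess_robust_to_gross_outliers(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 10, 100)
        y = 0.5 * x + rng.normal(0, 0.05, 100)
        y[10] += 25.0  # gross outlier
        grid = np.array([float(x[10])])
        fit = robust_loess(x, y, grid)
        assert abs(fit[0] - 0.5 * x[10]) < 0.3
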