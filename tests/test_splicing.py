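"""Exon usage, splicing index, within-gene F-test, event classification."""

import numpy as np
import pandas as pd
import pytest

import amniotx as ax
from amniotx.containers import MIDTRIMESTER, TERM, ExpressionSet, Feature, GeneModel, SampleSheet


def _sheet(n_a, n_b):
    groups = [MIDTRIMESTER] * n_a + [TERM] * n_b
    return SampleSheet(
        pd.DataFrame(
            {"group": groups, "ga_weeks": [20.0] * n_a + [39.0] * n_b},
            index=pd.Index([f"S{i}" for i in range(n_a + n_b)], name="sample_id"),
        )
    )


def _toy_model(n_exons=2, strand="+"):
    feats = {
        f"g1_E{i}": Feature(f"g1_E{i}", "g1", "Chr1", 100 + 300 * i, 250 + 300 * i, strand)
        for i in range(n_exons)
    }
    return GeneModel(feats, {"g1_T1": list(feats)})


class TestExonUsage:
    def test_direct_arithmetic(self):
        model = _toy_model()
        exon = ExpressionSet(
            pd.DataFrame({"S0": [7.0, 5.0]}, index=["g1_E0", "g1_E1"]), level="exon"
        )
        gene = ExpressionSet(pd.DataFrame({"S0": [6.0]}, index=["g1"]))
        u = ax.exon_usage(exon, gene, model)
        assert u.loc["g1_E0", "S0"] == 1.0
        assert u.loc["g1_E1", "S0"] == -1.0

    def test_equal_exon_and_gene_value_gives_zero(self):
        model = _toy_model(1)
        exon = ExpressionSet(pd.DataFrame({"S0": [5.0]}, index=["g1_E0"]), level="exon")
        gene = ExpressionSet(pd.DataFrame({"S0": [5.0]}, index=["g1"]))
        assert ax.exon_usage(exon, gene, model).loc["g1_E0", "S0"] == 0.0

    def test_shift_invariance_per_sample(self):
        model = _toy_model()
        exon_v = pd.DataFrame({"S0": [7.0, 5.0], "S1": [6.0, 4.0]}, index=["g1_E0", "g1_E1"])
        gene_v = pd.DataFrame({"S0": [6.0], "S1": [5.0]}, index=["g1"])
        u1 = ax.exon_usage(ExpressionSet(exon_v, level="exon"), ExpressionSet(gene_v), model)
        exon_v2, gene_v2 = exon_v.copy(), gene_v.copy()
        exon_v2["S0"] += 3.0
        gene_v2["S0"] += 3.0
        u2 = ax.exon_usage(ExpressionSet(exon_v2, level="exon"), ExpressionSet(gene_v2), model)
        assert np.allclose(u1.to_numpy(), u2.to_numpy())

    def test_orphan_exon_rejected(self):
        model = _toy_model()
        exon = ExpressionSet(pd.DataFrame({"S0": [7.0]}, index=["g1_E0"]), level="exon")
        gene = ExpressionSet(pd.DataFrame({"S0": [6.0]}, index=["other_gene"]))
        with pytest.raises(KeyError):
            ax.exon_usage(exon, gene, model)


class TestSplicingIndex:
    def test_two_exon_toy_gives_plus_minus_two_fold(self):
        """A: usages (0, 0); B: usages (+1, -1) -> si_fold = (+2, -2)."""
        sheet = _sheet(4, 4)
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1e-9, (2, 8))  # numerically tiny noise keeps variances positive
        base[0, 4:] += 1.0
        base[1, 4:] -= 1.0
        usage = pd.DataFrame(base, index=["g1_E0", "g1_E1"], columns=sheet.sample_ids)
        design = ax.build_design(sheet, ["group"], "group")
        si = ax.splicing_index_test(usage, design)
        assert si.loc["g1_E0", "si_fold"] == pytest.approx(2.0)
        assert si.loc["g1_E1", "si_fold"] == pytest.approx(-2.0)
        assert si.loc["g1_E0", "si_log2"] == pytest.approx(1.0)

    def test_identical_group_means_give_zero_si(self):
        sheet = _sheet(3, 3)
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1e-9, 6)  # same per-sample noise in both rows keeps group means equal
        usage = pd.DataFrame(
            np.array([0.5 + noise, -0.5 + noise]), index=["g1_E0", "g1_E1"], columns=sheet.sample_ids
        )
        si = ax.splicing_index_test(usage, ax.build_design(sheet, ["group"], "group"))
        assert np.allclose(si["si_log2"].to_numpy(), 0.0, atol=1e-8)

    def test_tiny_group_rejected(self):
        sheet = _sheet(1, 5)
        usage = pd.DataFrame(np.zeros((2, 6)), index=["a", "b"], columns=sheet.sample_ids)
        with pytest.raises(ValueError, match="2 samples"):
            ax.splicing_index_test(usage, ax.build_design(sheet, ["group"], "group"))

    def test_planted_cassette_power(self):
        """|SI log2| = 1.5 cassettes at n=15/15, noise 0.3: >=90% of planted
        exons pass q<0.05 and |fold|>2."""
        cfg = ax.CohortConfig(
            n_group_a=15, n_group_b=15, n_genes=400, noise_sd=0.3,
            frac_de=0.0, frac_spliced=0.15, splice_si_log2=1.5,
            splice_event_mix={"cassette": 1.0, "mutually_exclusive": 0, "alt5": 0, "alt3": 0, "intron_retention": 0},
            seed=21,
        )
        exon_es, gene_es, model, sheet, truth = ax.generate_cohort(cfg)
        design = ax.build_design(sheet, ["group"], "group")
        usage = ax.exon_usage(exon_es, gene_es, model)
        calls = ax.call_splicing(ax.splicing_index_test(usage, design), model)
        planted = [fid for t in truth for fid in t.affected_feature_ids]
        hit = calls.loc[planted, "significant"].mean()
        assert hit >= 0.9


class TestDiffspliceF:
    def _fit(self, usage_like, sheet, prior_df=None):
        design = ax.build_design(sheet, ["group"], "group")
        return ax.fit_moderated(usage_like, design, prior_df=prior_df), design

    def test_uniform_exon_fold_changes_give_zero_F(self):
        sheet = _sheet(4, 4)
        model = _toy_model(3)
        x = np.zeros((3, 8))
        x[:, 4:] = 1.0  # all exons shift identically
        es = pd.DataFrame(x, index=list(model.features), columns=sheet.sample_ids)
        fit, _ = self._fit(es, sheet, prior_df=0)
        table, _ = ax.diffsplice_ftest(fit, model)
        assert table.loc["g1", "F"] == pytest.approx(0.0, abs=1e-20)
        assert table.loc["g1", "p"] == pytest.approx(1.0)

    def test_two_exon_toy_equals_between_exon_mean_square(self):
        """Equal weights, betas (+1, -1), unit variance scale -> F = 2."""
        sheet = _sheet(50, 50)
        model = _toy_model(2)
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1e-9, (2, 100))
        x[0, 50:] += 1.0
        x[1, 50:] -= 1.0
        es = pd.DataFrame(x, index=list(model.features), columns=sheet.sample_ids)
        # prior_df=inf pools variances, so both exons carry equal weight
        fit, design = self._fit(es, sheet, prior_df=np.inf)
        j = list(design.matrix.columns).index(design.contrast)
        xm = design.matrix.to_numpy()
        v = np.linalg.inv(xm.T @ xm)[j, j]
        beta = fit.log2fc.to_numpy()
        w = 1.0 / (v * fit.s2_post.to_numpy())
        assert w[0] == pytest.approx(w[1])
        bbar = np.sum(w * beta) / np.sum(w)
        # equal weights + betas (+1, -1): weighted mean 0, and F normalized to
        # unit variance scale equals the between-exon mean square = 2
        assert bbar == pytest.approx(0.0, abs=1e-6)
        table, _ = ax.diffsplice_ftest(fit, model)
        expected = np.sum(w * (beta - bbar) ** 2) / (2 - 1)
        assert table.loc["g1", "F"] == pytest.approx(expected, rel=1e-10)
        assert table.loc["g1", "F"] * (v * fit.s2_post.iloc[0]) == pytest.approx(2.0, rel=1e-3)

    def test_single_exon_gene_is_untestable(self):
        sheet = _sheet(4, 4)
        feats = dict(_toy_model(2).features)
        feats["g2_E0"] = Feature("g2_E0", "g2", "Chr2", 100, 200, "+")
        model = GeneModel(feats, {})
        es = pd.DataFrame(np.random.default_rng(0).normal(0, 1, (3, 8)),
                          index=list(feats), columns=sheet.sample_ids)
        fit, _ = self._fit(es, sheet)
        table, untestable = ax.diffsplice_ftest(fit, model)
        assert untestable == ["g2"]
        assert "g2" not in table.index

    def test_si_and_f_test_agree_on_planted_events(self, small_cohort, group_design):
        exon_es, gene_es, model, sheet, truth = small_cohort
        usage = ax.exon_usage(exon_es, gene_es, model)
        calls = ax.call_splicing(ax.splicing_index_test(usage, group_design), model)
        gene_f, _ = ax.diffsplice_ftest(ax.fit_moderated(exon_es, group_design), model)
        si_genes = set(calls.loc[calls["significant"], "gene_id"])
        f_genes = set(gene_f.index[gene_f["q"] < 0.05])
        assert len(si_genes & f_genes) / len(si_genes) >= 0.8


class TestEventClassification:
    @staticmethod
    def _records(model, si: dict[str, float]):
        recs = pd.DataFrame(
            {
                "gene_id": [model.gene_of(f) for f in si],
                "si_log2": list(si.values()),
                "significant": [abs(v) > 1 for v in si.values()],
            },
            index=pd.Index(list(si), name="feature_id"),
        )
        return recs

    def test_cassette_from_transcript_absence(self):
        feats = {
            f"g1_E{i}": Feature(f"g1_E{i}", "g1", "Chr1", 100 + 300 * i, 250 + 300 * i, "+")
            for i in range(3)
        }
        model = GeneModel(feats, {"T1": ["g1_E0", "g1_E1", "g1_E2"], "T2": ["g1_E0", "g1_E2"]})
        recs = self._records(model, {"g1_E0": 0.0, "g1_E1": 1.5, "g1_E2": 0.0})
        assert ax.classify_events(recs, model).loc["g1_E1"] == "cassette"

    def test_intron_retention_requires_positive_shift(self):
        feats = {
            "g1_E0": Feature("g1_E0", "g1", "Chr1", 100, 250, "+"),
            "g1_E1": Feature("g1_E1", "g1", "Chr1", 400, 550, "+"),
            "g1_I0": Feature("g1_I0", "g1", "Chr1", 260, 390, "+", "intronic"),
        }
        model = GeneModel(feats, {"T1": ["g1_E0", "g1_E1"]})
        up = self._records(model, {"g1_E0": 0.0, "g1_E1": 0.0, "g1_I0": 1.3})
        down = self._records(model, {"g1_E0": 0.0, "g1_E1": 0.0, "g1_I0": -1.3})
        assert ax.classify_events(up, model).loc["g1_I0"] == "intron_retention"
        assert ax.classify_events(down, model).loc["g1_I0"] == "unassigned"

    def test_mutually_exclusive_needs_opposite_signs_and_no_cooccurrence(self):
        feats = {
            f"g1_E{i}": Feature(f"g1_E{i}", "g1", "Chr1", 100 + 300 * i, 250 + 300 * i, "+")
            for i in range(4)
        }
        model = GeneModel(
            feats,
            {"T1": ["g1_E0", "g1_E1", "g1_E3"], "T2": ["g1_E0", "g1_E2", "g1_E3"]},
        )
        recs = self._records(model, {"g1_E0": 0.0, "g1_E1": 1.4, "g1_E2": -1.4, "g1_E3": 0.0})
        ev = ax.classify_events(recs, model)
        assert ev.loc["g1_E1"] == "mutually_exclusive"
        assert ev.loc["g1_E2"] == "mutually_exclusive"

    @pytest.mark.parametrize("strand,expected", [("+", "alt5"), ("-", "alt3")])
    def test_alt_site_labels_swap_with_strand(self, strand, expected):
        """A variable genomic end is a donor (5') variant on '+' and an
        acceptor (3') variant on '-'."""
        feats = {
            "g1_E0": Feature("g1_E0", "g1", "Chr1", 100, 250, strand),
            "g1_E1": Feature("g1_E1", "g1", "Chr1", 400, 550, strand),
            "g1_E1x": Feature("g1_E1x", "g1", "Chr1", 400, 630, strand),
            "g1_E2": Feature("g1_E2", "g1", "Chr1", 700, 850, strand),
        }
        model = GeneModel(
            feats,
            {"T1": ["g1_E0", "g1_E1", "g1_E2"], "T2": ["g1_E0", "g1_E1x", "g1_E2"]},
        )
        recs = self._records(
            model, {"g1_E0": 0.0, "g1_E1": 0.0, "g1_E1x": 1.6, "g1_E2": 0.0}
        )
        assert ax.classify_events(recs, model).loc["g1_E1x"] == expected

    def test_no_transcript_disagreement_falls_through_to_unassigned(self):
        model = _toy_model(3)
        recs = self._records(
            model, {"g1_E0": 1.2, "g1_E1": 1.2, "g1_E2": 1.2}
        )
        ev = ax.classify_events(recs, model)
        assert (ev == "unassigned").all()

    def test_planted_events_recovered_end_to_end(self, small_cohort, group_design):
        exon_es, gene_es, model, sheet, truth = small_cohort
        usage = ax.exon_usage(exon_es, gene_es, model)
        calls = ax.call_splicing(ax.splicing_index_test(usage, group_design), model)
        events = ax.classify_events(calls, model)
        correct = total = 0
        for t in truth:
            if t.effect_kind != "splice":
                continue
            for fid in t.affected_feature_ids:
                if fid in events.index:
                    total += 1
                    correct += events.loc[fid] == t.event_type
        assert total > 20
        assert correct / total >= 0.9


def test_uniform_de_gene_shows_no_splicing_signal(small_cohort, group_design):
    """Gene-wide expression shifts cancel in usage: DE genes have si ~ 0."""
    exon_es, gene_es, model, sheet, truth = small_cohort
    usage = ax.exon_usage(exon_es, gene_es, model)
    si = ax.splicing_index_test(usage, group_design)
    de_features = [
        fid for t in truth if t.effect_kind.startswith("de") for fid in t.affected_feature_ids
    ]
    assert si.loc[de_features, "si_log2"].abs().max() < 0.75
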