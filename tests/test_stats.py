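"""ANOVA, Tukey HSD, Spearman correlation and disease comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

from gsisevo import (
    PathwayCode,
    PhyloClass,
    ProteinRecord,
    assign_anova_groups,
    disease_comparisons,
    divergence_anova,
    multifactor_anova,
    spearman_correlation,
    tukey_hsd,
)


def _rec(abbrev, sim, pathway="G", cls="U", disease=False, selected=False):
    return ProteinRecord(
        abbrev,
        f"P{abs(hash(abbrev)) % 100000:05d}",
        (PathwayCode(pathway),),
        PhyloClass(cls),
        sim,
        disease_omim=((("123456", "synthetic disease"),) if disease else ()),
        positive_selection_episodes=((("Theria", 166.0),) if selected else ()),
    )


class TestGroupAssignment:
    def test_first_listed_code_rules(self, gsis69):
        six = assign_anova_groups(gsis69.records, "six_group")
        assert six["CS"] == "T"  # "T, P" takes the first-listed code
        assert six["GK"] == "G"
        assert six["OGC"] == "PN"
        assert six["AAC"] == "M"

    def test_figure3_scheme_merges_tpn(self, gsis69):
        five = assign_anova_groups(gsis69.records, "five_group_figure3")
        assert five["OGC"] == "TPN"
        assert five["CS"] == "TPN"
        assert five["GK"] == "G"
        assert set(five.values()) == {"G", "M", "R", "S", "TPN"}

    def test_six_group_sizes(self, gsis69):
        six = assign_anova_groups(gsis69.records, "six_group")
        sizes = {g: sum(1 for v in six.values() if v == g) for g in set(six.values())}
        assert sizes == {"G": 11, "T": 16, "PN": 10, "M": 2, "R": 24, "S": 6}

    def test_unknown_scheme(self, gsis69):
        with pytest.raises(ValueError):
            assign_anova_groups(gsis69.records, "nope")


class TestDivergenceAnova:
    def test_network_pathway_effect(self, gsis69):
        grouping = assign_anova_groups(gsis69.records, "six_group")
        res = divergence_anova(gsis69.records, grouping)
        assert res.df_between == 5
        assert res.df_within == 63
        assert res.f_statistic > 5
        assert res.p < 0.001

    def test_degenerate_zero_variance_errors(self):
        recs = [_rec("a", 90.0), _rec("b", 90.0), _rec("c", 90.0, "T"), _rec("d", 90.0, "T")]
        grouping = {r.abbrev: r.primary_pathway.value for r in recs}
        with pytest.raises(ValueError):
            divergence_anova(recs, grouping)

    def test_single_group_errors(self):
        recs = [_rec("a", 90.0), _rec("b", 91.0)]
        with pytest.raises(ValueError):
            divergence_anova(recs, {"a": "G", "b": "G"})

    def test_two_groups_f_equals_squared_t(self, rng):
        """For two groups the one-way F is exactly the squared pooled t."""
        for _ in range(5):
            x = rng.normal(90, 3, size=8)
            y = rng.normal(93, 3, size=11)
            recs = [_rec(f"x{i}", round(min(v, 100.0), 6)) for i, v in enumerate(x)]
            recs += [_rec(f"y{i}", round(min(v, 100.0), 6), "T") for i, v in enumerate(y)]
            grouping = {r.abbrev: r.primary_pathway.value for r in recs}
            res = divergence_anova(recs, grouping)
            t = sps.ttest_ind(
                [r.hm_similarity for r in recs[:8]],
                [r.hm_similarity for r in recs[8:]],
                equal_var=True,
            )
            assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-9)
            assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_multifactor_sequential_class_effect(self, gsis69):
        """After pathway enters the model first, the age-class effect is far
        from significance (the published adjusted P is 0.46)."""
        grouping = assign_anova_groups(gsis69.records, "six_group")
        table = multifactor_anova(
            gsis69.records, grouping,
            factors=("pathway", "phylo_class", "positive_selection", "disease"),
        )
        p_class = float(table.loc["C(phylo_class)", "PR(>F)"])
        assert p_class == pytest.approx(0.46, abs=0.02)


class TestTukey:
    def test_network_pairwise_structure(self, gsis69):
        grouping = assign_anova_groups(gsis69.records, "six_group")
        res = tukey_hsd(gsis69.records, grouping, alpha=0.05)
        sig = {frozenset((a, b)) for a, b, _, _ in res.significant()}
        assert {frozenset(p) for p in [("S", "G"), ("S", "T"), ("R", "G"), ("R", "T"), ("S", "PN")]} <= sig
        # The lower-conservation coalitions are S and R.
        means = divergence_anova(gsis69.records, grouping).group_means
        assert means["S"] < means["G"] and means["R"] < means["G"]

    def test_identical_groups_not_significant(self):
        recs = [_rec(f"a{i}", 90.0 + i) for i in range(5)]
        recs += [_rec(f"b{i}", 90.0 + i, "T") for i in range(5)]
        grouping = {r.abbrev: r.primary_pathway.value for r in recs}
        res = tukey_hsd(recs, grouping)
        assert all(p > 0.9 for _, _, _, p in res.pairs)

    def test_shifted_group_significant_vs_both_others(self, rng):
        base = rng.normal(90, 1, size=10)
        recs = [_rec(f"a{i}", float(np.clip(v, 0, 100))) for i, v in enumerate(base)]
        recs += [_rec(f"b{i}", float(np.clip(v, 0, 100)), "T") for i, v in enumerate(rng.normal(90, 1, 10))]
        recs += [_rec(f"c{i}", float(np.clip(v - 10, 0, 100)), "S") for i, v in enumerate(rng.normal(90, 1, 10))]
        grouping = {r.abbrev: r.primary_pathway.value for r in recs}
        res = tukey_hsd(recs, grouping)
        assert res.p_adjusted("G", "S") < 0.001
        assert res.p_adjusted("S", "T") < 0.001
        assert res.p_adjusted("G", "T") > 0.05

    def test_adjusted_p_not_below_unadjusted_pairwise(self, gsis69):
        """Tukey's studentized-range p is never smaller than the unadjusted
        pairwise p from the same pooled-error model (Fisher LSD)."""
        grouping = assign_anova_groups(gsis69.records, "six_group")
        res = tukey_hsd(gsis69.records, grouping)
        values = {g: [] for g in set(grouping.values())}
        for r in gsis69.records:
            values[grouping[r.abbrev]].append(r.hm_similarity)
        n_total = sum(len(v) for v in values.values())
        df_within = n_total - len(values)
        mse = sum(
            ((np.asarray(v) - np.mean(v)) ** 2).sum() for v in values.values()
        ) / df_within
        for a, b, diff, p_adj in res.pairs:
            se = np.sqrt(mse * (1 / len(values[a]) + 1 / len(values[b])))
            p_lsd = 2 * sps.t.sf(abs(diff) / se, df=df_within)
            assert p_adj >= p_lsd - 1e-9


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        dn = spearman_correlation([1, 2, 3, 4], [40, 30, 20, 10])
        assert up.rho == pytest.approx(1.0)
        assert dn.rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = spearman_correlation(x, y)
        expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(expected)
        assert res.p_two_tailed == pytest.approx(sps.spearmanr(x, y).pvalue, abs=1e-9)

    def test_exact_small_n_agrees_with_scipy_permutation(self):
        x, y = [1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5]
        res = spearman_correlation(x, y)
        ref = sps.permutation_test(
            (x,), lambda xs: sps.spearmanr(xs, y).statistic,
            permutation_type="pairings", alternative="two-sided",
        )
        assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(1, 10, size=15)
        y = rng.uniform(1, 10, size=15)
        base = spearman_correlation(x, y)
        assert spearman_correlation(np.log(x), y).rho == pytest.approx(base.rho)
        assert spearman_correlation(x, y**3).rho == pytest.approx(base.rho)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestDiseaseComparisons:
    def test_network_disease_contrast(self, gsis69):
        res = disease_comparisons(gsis69.records)
        assert res["n_disease"] == 24
        assert res["mean_disease"] == pytest.approx(95.1, abs=0.15)
        assert res["mean_other"] == pytest.approx(93.1, abs=0.15)
        assert res["t_p"] == pytest.approx(0.07, abs=0.02)
        assert res["n_disease_universal"] == 20

    def test_identical_arms_p_one(self):
        recs = [_rec(f"d{i}", 90.0 + i, disease=True) for i in range(5)]
        recs += [_rec(f"o{i}", 90.0 + i) for i in range(5)]
        res = disease_comparisons(recs)
        assert res["t_p"] == pytest.approx(1.0)
        # All records Universal and none selected: the chi-squared contrasts
        # are undefined and surfaced as NaN rather than a spurious p.
        assert np.isnan(res["class_chi2_p"]) and np.isnan(res["possel_chi2_p"])

    def test_selection_deficit_table(self, gsis69):
        """Only one of the nine positively selected genes is a disease gene;
        the 2x2 chi-squared on the printed margins is ~2.56 (1 df)."""
        res = disease_comparisons(gsis69.records)
        assert res["possel_chi2"] == pytest.approx(2.56, abs=0.01)

    def test_too_few_in_one_arm_errors(self):
        recs = [_rec("d0", 95.0, disease=True)] + [_rec(f"o{i}", 90.0) for i in range(4)]
        with pytest.raises(ValueError):
            disease_comparisons(recs)
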