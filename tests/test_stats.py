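import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from ramanfp import (
    AlphaPolicy,
    CohortTable,
    correlate_ratios_with_phenotypes,
    holm_adjust,
    pearson_with_p,
    two_way_anova,
)
from ramanfp.bands import RatioTable

from oracles import anova_type2_f, holm_stepwise, pearson_direct


class TestPearson:
    def test_affine_dependence_is_perfect(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-300

    def test_negation_flips_sign(self):
        x = np.arange(8.0)
        r, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula_and_scipy(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        r, p = pearson_with_p(x, y)
        r0, p0 = pearson_direct(x, y)
        assert r == pytest.approx(r0, rel=1e-12)
        assert p == pytest.approx(p0, rel=1e-12)
        r1, p1 = pearsonr(x, y)
        assert r == pytest.approx(r1, rel=1e-10)
        assert p == pytest.approx(p1, rel=1e-8)

    def test_affine_rescaling_invariance(self, rng):
        x = rng.random(20)
        y = rng.random(20)
        r, p = pearson_with_p(x, y)
        r2, p2 = pearson_with_p(3.0 * x - 7.0, 0.5 * y + 2.0)
        assert r2 == pytest.approx(r, rel=1e-12)
        assert p2 == pytest.approx(p, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_with_p(np.ones(5), np.arange(5.0))

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="3 observations"):
            pearson_with_p(np.arange(2.0), np.arange(2.0))


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.03]), [0.03])

    def test_worked_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_four_equal_values_propagate(self):
        np.testing.assert_allclose(holm_adjust([0.05] * 4), [0.2] * 4)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            holm_adjust(bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_matches_stepwise_definition_and_is_monotone(self, pvals):
        adj = holm_adjust(pvals)
        np.testing.assert_allclose(adj, holm_stepwise(np.array(pvals)), rtol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # order preserved


class TestTwoWayAnova:
    def test_constant_response_gives_null_f(self):
        res = two_way_anova(np.ones(12), np.repeat(["a", "b"], 6), np.tile(["x", "y", "z"], 4))
        for term in ("group", "timepoint", "group:timepoint"):
            assert res.table.loc[term, "F"] == 0.0
            assert res.table.loc[term, "p"] == 1.0

    def test_additive_means_have_zero_interaction(self):
        a = np.repeat(["a1", "a2"], 4)
        b = np.tile(["b1", "b2"], 4)
        effect_a = np.where(a == "a1", 0.0, 2.0)
        effect_b = np.where(b == "b1", 0.0, 5.0)
        res = two_way_anova(1.0 + effect_a + effect_b, a, b)
        assert res.table.loc["group:timepoint", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("balanced", [True, False])
    def test_f_matches_dense_nested_least_squares(self, rng, balanced):
        if balanced:
            a = np.repeat(["a1", "a2"], 9)
            b = np.tile(["b1", "b2", "b3"], 6)
        else:
            cells = [("a1", "b1", 3), ("a1", "b2", 5), ("a1", "b3", 2),
                     ("a2", "b1", 4), ("a2", "b2", 2), ("a2", "b3", 6)]
            a = np.concatenate([[ai] * n for ai, _, n in cells])
            b = np.concatenate([[bi] * n for _, bi, n in cells])
        y = rng.normal(size=len(a))
        res = two_way_anova(y, a, b)
        oracle = anova_type2_f(y, a, b)
        for term, key in (("group", "A"), ("timepoint", "B"), ("group:timepoint", "A:B")):
            assert res.table.loc[term, "F"] == pytest.approx(oracle[key], rel=1e-8)

    def test_df_decomposition(self, rng):
        a = np.repeat(["a1", "a2"], 9)
        b = np.tile(["b1", "b2", "b3"], 6)
        res = two_way_anova(rng.normal(size=18), a, b)
        assert res.table["df"].sum() == len(a) - 1

    def test_balanced_type2_recovers_total_sum_of_squares(self, rng):
        a = np.repeat(["a1", "a2"], 9)
        b = np.tile(["b1", "b2", "b3"], 6)
        y = rng.normal(size=18)
        res = two_way_anova(y, a, b)
        total = float(np.sum((y - y.mean()) ** 2))
        assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_single_level_factor_redirects_to_one_way(self):
        with pytest.raises(ValueError, match="1-way"):
            two_way_anova(np.arange(6.0), ["a"] * 6, np.tile(["x", "y"], 3))

    def test_posthoc_is_holm_adjusted_family(self, rng):
        a = np.tile(np.repeat(["g1", "g2", "g3"], 3), 2)
        b = np.repeat(["t1", "t2"], 9)
        res = two_way_anova(rng.normal(size=18), a, b)
        assert len(res.posthoc) == 6  # 3 pairs x 2 timepoints
        assert (res.posthoc["p_holm"] >= res.posthoc["p_raw"] - 1e-15).all()


def make_tables(rng, n=12):
    ids = [f"s{i}" for i in range(n)]
    ratios = pd.DataFrame(
        {
            "lipid_protein": rng.random(n) + 0.5,
            "nucleic_acid_lipid": rng.random(n) + 0.5,
            "tissue_fibrosis": rng.random(n) + 0.2,
            "collagen_denaturation": rng.random(n) + 0.2,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    cohort = CohortTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "group": ["g1", "g2", "g3"] * (n // 3),
                "timepoint": ["4d"] * n,
                "grip_strength": 800.0 - 600.0 * ratios["lipid_protein"].to_numpy(),
                "col1_area": rng.random(n),
                "sirius_red": rng.random(n),
            }
        )
    )
    return RatioTable(ratios), cohort


class TestCorrelateRatiosWithPhenotypes:
    def test_default_pair_family(self, rng):
        ratios, cohort = make_tables(rng)
        res = correlate_ratios_with_phenotypes(ratios, cohort)
        assert [(c.ratio, c.phenotype) for c in res] == [
            ("lipid_protein", "grip_strength"),
            ("nucleic_acid_lipid", "grip_strength"),
            ("tissue_fibrosis", "col1_area"),
            ("collagen_denaturation", "sirius_red"),
        ]

    def test_deterministic_phenotype_correlates_perfectly(self, rng):
        ratios, cohort = make_tables(rng)
        res = correlate_ratios_with_phenotypes(ratios, cohort)
        by = {(c.ratio, c.phenotype): c for c in res}
        c = by[("lipid_protein", "grip_strength")]
        assert c.r == pytest.approx(-1.0, abs=1e-10)
        assert c.significant(AlphaPolicy())

    def test_missing_phenotypes_dropped_pairwise(self, rng):
        ratios, cohort = make_tables(rng)
        cohort.data.loc[0:1, "grip_strength"] = np.nan
        res = correlate_ratios_with_phenotypes(ratios, cohort)
        by = {(c.ratio, c.phenotype): c for c in res}
        assert by[("lipid_protein", "grip_strength")].n == 10
        assert by[("tissue_fibrosis", "col1_area")].n == 12

    def test_unknown_pair_named_in_error(self, rng):
        ratios, cohort = make_tables(rng)
        with pytest.raises(ValueError, match="nonexistent"):
            correlate_ratios_with_phenotypes(ratios, cohort, pairs=[("nonexistent", "grip_strength")])

    def test_holm_flag_attaches_adjusted_p(self, rng):
        ratios, cohort = make_tables(rng)
        res = correlate_ratios_with_phenotypes(ratios, cohort, adjust=True)
        raw = [c.p for c in res]
        np.testing.assert_allclose([c.p_adjusted for c in res], holm_stepwise(np.array(raw)), rtol=1e-12)
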