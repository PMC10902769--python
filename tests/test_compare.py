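import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mealrecall.compare import (
    GuidelineEntry,
    GuidelineTable,
    add_percent_tei_columns,
    bland_altman,
    classify_guidelines,
    cross_classify_quartiles,
    effect_size,
    guideline_agreement,
    percent_difference,
    run_comparison,
    spearman,
    summarize_differences,
    wilcoxon_signed_rank,
)
from mealrecall.nutrients import Basis, NutrientVector


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def wilcoxon_p_by_enumeration(d):
    """Exact two-sided P over all 2^n sign assignments of |d| ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = np.array(
        [
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product((0, 1), repeat=len(d))
        ]
    )
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def spearman_by_midrank_pearson(a, b):
    ra, rb = sps.rankdata(a), sps.rankdata(b)
    ra_c, rb_c = ra - ra.mean(), rb - rb.mean()
    return float(
        (ra_c * rb_c).sum() / np.sqrt((ra_c**2).sum() * (rb_c**2).sum())
    )


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_antisymmetric_differences(self):
        b = np.zeros(6)
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.statistic == pytest.approx(6 * 7 / 4)
        assert res.p_value == pytest.approx(1.0)
        assert res.z == 0.0

    def test_n6_fixed_vector_matches_enumeration(self):
        d = np.array([1.3, -0.4, 2.2, 0.6, -1.9, 3.1])
        res = wilcoxon_signed_rank(d, np.zeros(6))
        assert res.exact
        assert res.p_value == pytest.approx(wilcoxon_p_by_enumeration(d))

    def test_all_positive_n5_exact_tails(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(d, np.zeros(5))
        assert res.exact
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(2 / 32)  # two-sided 1/16

    @pytest.mark.parametrize("case", range(50))
    def test_random_small_instances_match_enumeration(self, case):
        rng = np.random.default_rng(200 + case)
        n = int(rng.integers(3, 11))
        d = rng.normal(size=n)
        res = wilcoxon_signed_rank(d, np.zeros(n))
        assert res.p_value == pytest.approx(wilcoxon_p_by_enumeration(d), abs=1e-12)

    def test_zero_differences_discarded(self):
        a = np.array([1.0, 2.0, 3.0, 5.0])
        b = np.array([1.0, 2.0, 1.0, 2.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.n_nonzero == 2
        assert res.n_total == 4

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("case", range(15))
    def test_normal_path_close_to_exact_at_n15(self, case):
        rng = np.random.default_rng(300 + case)
        d = rng.normal(0.3, 1.0, size=15)
        exact = wilcoxon_signed_rank(d, np.zeros(15), exact_max_n=25)
        approx = wilcoxon_signed_rank(d, np.zeros(15), exact_max_n=0)
        assert exact.exact and not approx.exact
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_ties_use_normal_path_with_correction(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, -3.0, 4.0, 4.0])
        res = wilcoxon_signed_rank(d, np.zeros(8))
        assert not res.exact
        # scipy's tie-corrected normal approximation agrees
        ref = sps.wilcoxon(d, correction=True, mode="approx")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)


class TestEffectSize:
    def test_zero_z(self):
        r, label = effect_size(0.0, 100)
        assert r == 0.0 and label == "negligible"

    @pytest.mark.parametrize(
        "r,expected",
        [(0.107, "small"), (0.398, "moderate"), (0.723, "large"),
         (0.05, "negligible"), (0.3, "moderate"), (0.5, "large")],
    )
    def test_labels_at_cutoffs(self, r, expected):
        n = 161
        z = r * np.sqrt(n)
        got_r, label = effect_size(z, n)
        assert got_r == pytest.approx(r)
        assert label == expected


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

class TestBlandAltman:
    def test_identical_methods(self):
        a = np.array([1.0, 2.0, 3.0])
        mean, lo, hi, n_within, prop = bland_altman(a, a)
        assert mean == 0.0 and lo == 0.0 and hi == 0.0
        assert n_within == 3 and prop == 1.0

    def test_hand_computed(self):
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([1.0, 1.0, 1.0])
        mean, lo, hi, n_within, _ = bland_altman(a, b)  # d = -1, 0, 1
        assert mean == pytest.approx(0.0)
        assert lo == pytest.approx(-1.96)
        assert hi == pytest.approx(1.96)
        assert n_within == 3

    def test_midpoint_identity(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        mean, lo, hi, *_ = bland_altman(a, b)
        assert (lo + hi) / 2 == pytest.approx(mean)

    def test_sign_convention_a_minus_b(self):
        mean, *_ = bland_altman([10.0, 10.0], [12.0, 14.0])
        assert mean == pytest.approx(-3.0)

    def test_normal_differences_within_fraction_near_95pct(self):
        rng = np.random.default_rng(99)
        a = rng.normal(0, 1, 10_000)
        b = np.zeros(10_000)
        *_, prop = bland_altman(a, b)
        assert prop == pytest.approx(0.95, abs=0.01)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_agreement(self):
        rho, p, label = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert label == "good"

    def test_perfect_reversal(self):
        rho, _, label = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)
        assert label == "poor"

    def test_ties_match_direct_midrank_pearson(self):
        a = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, _, _ = spearman(a, b)
        assert rho == pytest.approx(spearman_by_midrank_pearson(a, b))

    @pytest.mark.parametrize("case", range(20))
    def test_matches_scipy_and_direct_formula(self, case):
        rng = np.random.default_rng(400 + case)
        n = int(rng.integers(5, 40))
        a = np.round(rng.normal(size=n), 1)  # rounding induces ties
        b = np.round(a + rng.normal(scale=2, size=n), 1)
        rho, p, _ = spearman(a, b)
        assert rho == pytest.approx(spearman_by_midrank_pearson(a, b), abs=1e-12)
        ref = sps.spearmanr(a, b)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    @pytest.mark.parametrize("rho,expected", [(0.1, "poor"), (0.2, "acceptable"), (0.49, "acceptable"), (0.5, "good")])
    def test_labels(self, rho, expected):
        # construct data achieving an approximate rho is fiddly; test the rule
        # through the cutoffs on synthetic monotone mixes instead
        from mealrecall.compare import SPEARMAN_CUTOFFS
        if rho < SPEARMAN_CUTOFFS[0]:
            assert expected == "poor"
        elif rho < SPEARMAN_CUTOFFS[1]:
            assert expected == "acceptable"
        else:
            assert expected == "good"

    def test_constant_column_is_error(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Cross-classification
# ---------------------------------------------------------------------------

class TestCrossClassify:
    def test_identical_values_full_exact(self):
        a = np.arange(1.0, 13.0)
        counts = cross_classify_quartiles(a, a)
        assert counts["exact"] == 12
        assert counts["exact_plus_adjacent"] == 12
        assert counts["disagreement"] == 0 and counts["extreme"] == 0

    def test_reversed_ranking_n8(self):
        a = np.arange(1.0, 9.0)
        b = a[::-1]
        counts = cross_classify_quartiles(a, b)
        assert counts["exact"] == 0
        assert counts["extreme"] == 4

    @pytest.mark.parametrize("case", range(20))
    def test_exact_plus_adjacent_superset_and_sum(self, case):
        rng = np.random.default_rng(500 + case)
        n = int(rng.integers(4, 60))
        a, b = rng.normal(size=n), rng.normal(size=n)
        counts = cross_classify_quartiles(a, b)
        assert counts["exact_plus_adjacent"] >= counts["exact"]
        adjacent_only = counts["exact_plus_adjacent"] - counts["exact"]
        assert counts["exact"] + adjacent_only + counts["disagreement"] + counts["extreme"] == n

    @pytest.mark.parametrize("case", range(10))
    def test_marginals_balanced_for_distinct_values(self, case):
        rng = np.random.default_rng(600 + case)
        n = int(rng.integers(8, 50))
        a = rng.permutation(np.linspace(1, 100, n))
        cuts = np.quantile(a, [0.25, 0.5, 0.75])
        bins = 1 + (a[:, None] > cuts[None, :]).sum(axis=1)
        counts = np.bincount(bins, minlength=5)[1:]
        assert counts.min() >= n // 4
        assert counts.max() <= -(-n // 4)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            cross_classify_quartiles([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Guidelines
# ---------------------------------------------------------------------------

class TestGuidelines:
    def test_middle_category(self):
        entry = GuidelineEntry("fiber_g", "absolute", (10.0, 20.0), ("low", "adequate", "high"))
        assert classify_guidelines({"fiber_g": 15.0}, entry) == "adequate"

    def test_boundary_belongs_to_lower(self):
        entry = GuidelineEntry("fiber_g", "absolute", (10.0, 20.0), ("low", "adequate", "high"))
        assert classify_guidelines({"fiber_g": 10.0}, entry) == "low"
        assert classify_guidelines({"fiber_g": 20.0}, entry) == "adequate"

    def test_g_per_kg_body_weight(self):
        entry = GuidelineEntry("protein_g", "g_per_kg_bw", (0.8, 2.0), ("low", "adequate", "high"))
        assert classify_guidelines({"protein_g": 70.0}, entry, weight_kg=70.0) == "adequate"

    def test_missing_weight_is_error(self):
        entry = GuidelineEntry("protein_g", "g_per_kg_bw", (0.8,), ("low", "adequate"))
        with pytest.raises(ValueError):
            classify_guidelines({"protein_g": 70.0}, entry)

    def test_percent_tei_unit(self):
        entry = GuidelineEntry("fat_g", "percent_tei", (20.0, 35.0),
                               ("low", "adequate", "high"), macro="total_fat")
        day = {"energy_kcal": 1800.0, "fat_g": 50.0}  # 25 %TEI
        assert classify_guidelines(day, entry) == "adequate"

    def test_salt_unit(self):
        entry = GuidelineEntry("sodium_mg", "salt_g", (6.0,), ("adequate", "high"))
        assert classify_guidelines({"sodium_mg": 2400.0}, entry) == "adequate"
        assert classify_guidelines({"sodium_mg": 2800.0}, entry) == "high"

    def test_table_validation(self):
        with pytest.raises(ValueError):
            GuidelineEntry("x", "absolute", (10.0, 5.0), ("a", "b", "c"))
        with pytest.raises(ValueError):
            GuidelineEntry("x", "absolute", (10.0,), ("a", "b", "c"))
        with pytest.raises(ValueError):
            GuidelineEntry("x", "bogus_unit", (10.0,), ("a", "b"))

    def test_packaged_example_table_loads(self):
        import json
        from importlib import resources

        raw = json.loads(
            (resources.files("mealrecall.data") / "guidelines_example.json").read_text()
        )
        table = GuidelineTable.from_dict(raw)
        assert len(table.entries) == 14
        two_level = {"saturated_fat", "salt", "fiber", "thiamin", "riboflavin"}
        for name, entry in table.entries.items():
            assert len(entry.labels) == (2 if name in two_level else 3)


class TestGuidelineAgreement:
    def test_all_identical(self):
        n, prop = guideline_agreement(["a", "b"], ["a", "b"])
        assert (n, prop) == (2, 1.0)

    def test_disjoint(self):
        n, prop = guideline_agreement(["a", "a"], ["b", "b"])
        assert (n, prop) == (0, 0.0)

    def test_seven_of_ten(self):
        a = ["low"] * 7 + ["high"] * 3
        b = ["low"] * 7 + ["low"] * 3
        n, prop = guideline_agreement(a, b)
        assert n == 7 and prop == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# Percentage differences
# ---------------------------------------------------------------------------

class TestPercentDifference:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (1569.9, 1715.3, 9.3),
            (71.8, 84.8, 18.1),
            (100.0, 100.0, 0.0),
        ],
    )
    def test_rows(self, a, b, expected):
        assert round(percent_difference(a, b), 1) == expected

    def test_zero_reference_is_error(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 5.0)


class TestSummarizeDifferences:
    def test_single_value(self):
        assert summarize_differences([-4.2]) == (4.2, 4.2, 4.2)

    def test_one_to_nine(self):
        med, q1, q3 = summarize_differences(list(range(1, 10)))
        assert (med, q1, q3) == (5.0, 3.0, 7.0)

    def test_absolute_values_used(self):
        med, _, _ = summarize_differences([-10.0, 10.0, -10.0])
        assert med == 10.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            summarize_differences([])


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _intake_frame(rng, n=40):
    df = pd.DataFrame(
        {
            "energy_kcal": rng.lognormal(7.4, 0.3, n),
            "protein_g": rng.lognormal(4.2, 0.3, n),
            "sodium_mg": rng.lognormal(7.4, 0.4, n),
        },
        index=[f"p{i:03d}" for i in range(n)],
    )
    df.index.name = "participant_id"
    return df


class TestRunComparison:
    def test_identical_tables(self, rng):
        a = _intake_frame(rng)
        result, summary = run_comparison(a, a.copy())
        assert (result["pct_diff"] == 0).all()
        assert np.allclose(result["spearman_rho"], 1.0)
        assert (result["q_exact"] == len(a)).all()
        assert summary["abs_pct_diff_median"] == 0.0

    def test_row_count_matches_nutrient_list(self, rng):
        a = _intake_frame(rng)
        result, _ = run_comparison(a, a * 1.1, nutrients=["energy_kcal", "sodium_mg"])
        assert list(result.index) == ["energy_kcal", "sodium_mg"]

    def test_participant_mismatch_names_ids(self, rng):
        a = _intake_frame(rng)
        b = a.drop(index="p003")
        with pytest.raises(ValueError, match="p003"):
            run_comparison(a, b)

    def test_multiplicative_bias_recovered_in_ba_mean(self):
        rng = np.random.default_rng(11)
        n, b_factor = 400, 1.2
        a = _intake_frame(rng, n)
        noise = np.exp(rng.normal(0, 0.05, (n, a.shape[1])))
        b = a * b_factor * noise
        result, _ = run_comparison(a, b)
        mean_energy = a["energy_kcal"].mean()
        expected_shift = mean_energy * (1 - b_factor)  # A - B < 0
        got = result.loc["energy_kcal", "ba_mean_diff"]
        # Monte-Carlo tolerance: 4 SEs of the difference mean
        d = a["energy_kcal"] - b["energy_kcal"]
        se = d.std() / np.sqrt(n)
        assert abs(got - expected_shift) < 4 * se + 0.05 * abs(expected_shift)
        assert got < 0

    def test_tei_columns_helper(self, rng):
        df = pd.DataFrame(
            {"energy_kcal": [2000.0], "protein_g": [100.0], "carbohydrate_g": [200.0],
             "sugar_g": [50.0], "fat_g": [70.0], "saturated_fat_g": [20.0],
             "monounsaturated_fat_g": [25.0], "polyunsaturated_fat_g": [10.0]},
            index=["p1"],
        )
        out = add_percent_tei_columns(df)
        assert out.loc["p1", "protein_pct_tei"] == pytest.approx(100 * 100 * 4 / 2000)
        assert out.loc["p1", "sugar_pct_tei"] == pytest.approx(100 * 50 * 3.75 / 2000)
        assert out.loc["p1", "total_fat_pct_tei"] == pytest.approx(100 * 70 * 9 / 2000)
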