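"""Statistical battery: reliability, group tests, correlation, cohort report."""

import numpy as np
import pytest

from adcaqp import (analyze_cohort, generate_cohort, icc_two_observers,
                    independent_t_test, ks_normality, lsd_posthoc,
                    one_way_anova, pearson)
from oracles import anova_f_oracle, icc_oracle, pearson_r_oracle, pooled_t_oracle


class TestICC:
    def test_perfect_agreement_is_one_and_good(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_two_observers(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0)
        assert res.reliability_label == "good"

    def test_independent_noise_is_near_zero_and_poor(self, rng):
        ratings = rng.standard_normal((400, 2))
        res = icc_two_observers(ratings)
        assert abs(res.icc) < 0.15
        assert res.reliability_label == "poor"

    def test_hand_sized_table_matches_mean_squares_oracle(self):
        table = [[9, 2], [1, 10], [8, 6], [2, 4], [7, 6]]
        res = icc_two_observers(table)
        assert res.icc == pytest.approx(icc_oracle(table), abs=1e-12)

    def test_label_rule_threshold(self):
        # a table tuned near the boundary still follows icc >= 0.75 exactly
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = icc_two_observers(np.column_stack([col, col + [0.1, -0.2, 0.3,
                                                             -0.1, 0.2, -0.3]]))
        assert res.reliability_label == ("good" if res.icc >= 0.75 else "poor")

    def test_zero_between_subject_variance_flagged_undefined(self):
        res = icc_two_observers(np.full((5, 2), 3.0))
        assert not res.defined
        assert res.reliability_label == "undefined"
        assert np.isnan(res.icc)

    def test_seeded_sweep_against_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 9))
            table = rng.integers(0, 10, size=(n, 2)).astype(float)
            if np.ptp(table.mean(axis=1)) == 0:
                continue
            res = icc_two_observers(table)
            assert res.icc == pytest.approx(icc_oracle(table), abs=1e-10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_two_observers([[1, 2], [3, 4]])

    def test_agrees_with_pingouin_icc2(self, rng):
        import pandas as pd
        import pingouin as pg

        table = rng.normal(5, 2, size=(12, 2))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": table.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        # two-way random absolute-agreement single-measures row (the Type
        # label changed across pingouin versions)
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[sel, "ICC"].iloc[0])
        assert icc_two_observers(table).icc == pytest.approx(icc2, abs=1e-8)


class TestNormalityAnovaT:
    def test_ks_near_zero_on_normal_grid(self):
        from scipy import stats as sps
        grid = sps.norm.ppf(np.linspace(0.01, 0.99, 200))
        stat, _ = ks_normality(grid)
        assert stat < 0.05

    def test_ks_rejects_uniform_sample(self, rng):
        stat, p = ks_normality(rng.uniform(0, 1, 500))
        assert p < 0.05

    def test_ks_input_guards(self, rng):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ks_normality([2.0] * 10)

    def test_anova_identical_constant_groups(self):
        f, p = one_way_anova([[3.0, 3.0], [3.0, 3.0, 3.0]])
        assert f == 0.0 and p == 1.0

    def test_anova_two_groups_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 15)
        f, pf = one_way_anova([a, b])
        t, pt = independent_t_test(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert pf == pytest.approx(pt, rel=1e-10)

    def test_anova_matches_sum_of_squares_oracle(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 5.0, 8.0]]
        f, _ = one_way_anova(groups)
        assert f == pytest.approx(anova_f_oracle(groups), abs=1e-12)

    def test_anova_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])

    def test_t_identical_groups(self):
        t, p = independent_t_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_t_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        t1, p1 = independent_t_test(a, b)
        t2, p2 = independent_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_t_matches_textbook_pooled_formula(self):
        a = [4.2, 5.1, 3.9, 4.8]
        b = [5.5, 6.1, 5.9, 6.4]
        t, _ = independent_t_test(a, b)
        assert t == pytest.approx(pooled_t_oracle(a, b), abs=1e-12)

    def test_welch_variant_differs_under_unequal_variance(self, rng):
        a = rng.normal(0, 0.5, 10)
        b = rng.normal(0, 4.0, 30)
        t_s, _ = independent_t_test(a, b, "student")
        t_w, _ = independent_t_test(a, b, "welch")
        assert t_s != pytest.approx(t_w)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            independent_t_test([1.0], [2.0, 3.0])


class TestLSD:
    def test_bonferroni_threshold_three_comparisons(self):
        groups = [[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]]
        _, threshold = lsd_posthoc(groups, family_alpha=0.05, n_comparisons=3)
        assert threshold == 0.017

    def test_identical_pair_has_t_zero_p_one(self):
        groups = [[2.0, 4.0, 3.0], [2.0, 4.0, 3.0], [7.0, 8.0, 9.0]]
        pairs, _ = lsd_posthoc(groups)
        first = next(p for p in pairs if p["pair"] == ("0", "1"))
        assert first["t"] == pytest.approx(0.0)
        assert first["p"] == pytest.approx(1.0)

    def test_pairwise_t_matches_pooled_ms_oracle(self):
        from scipy import stats as sps
        groups = [np.array([1.0, 2.0, 2.5]), np.array([3.0, 3.5, 4.0]),
                  np.array([6.0, 7.0, 8.0])]
        pairs, _ = lsd_posthoc(groups)
        ntot, k = 9, 3
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (ntot - k)
        for pr in pairs:
            i, j = int(pr["pair"][0]), int(pr["pair"][1])
            se = np.sqrt(msw * (1 / 3 + 1 / 3))
            t_hand = (groups[i].mean() - groups[j].mean()) / se
            assert pr["t"] == pytest.approx(t_hand, abs=1e-12)
            assert pr["p"] == pytest.approx(2 * sps.t.sf(abs(t_hand), ntot - k),
                                            abs=1e-12)

    def test_flags_derive_only_from_the_threshold(self):
        groups = [[1.0, 1.1, 0.9], [1.0, 1.2, 1.1], [9.0, 9.5, 10.0]]
        pairs, threshold = lsd_posthoc(groups, family_alpha=0.05)
        for pr in pairs:
            assert pr["significant"] == (pr["p"] < threshold)

    def test_nonpositive_comparison_count_rejected(self):
        with pytest.raises(ValueError):
            lsd_posthoc([[1.0, 2.0], [3.0, 4.0]], n_comparisons=0)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_product_moment_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            assert pearson(x, y)[0] == pytest.approx(pearson_r_oracle(x, y),
                                                     abs=1e-12)

    def test_sampling_band_at_planted_rho(self, rng):
        # seeded bivariate normal, rho = 0.35, n = 76: r should fall inside
        # the analytic Fisher-z 95% band in most replicates
        rho, n, hits, reps = 0.35, 76, 0, 100
        half = 1.96 / np.sqrt(n - 3)
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            r, _ = pearson(x, y)
            hits += abs(np.arctanh(r) - np.arctanh(rho)) <= half
        assert hits / reps >= 0.9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0, 3.0], [1.0, 2.0])


class TestCohortReport:
    def test_planted_correlation_recovered(self):
        df = generate_cohort(group_sizes=(13, 53, 10), planted_r=0.6,
                             differentiation_effect=False, seed=2)
        rep = analyze_cohort(df)
        row = rep["correlations"].set_index("feature").loc["p75"]
        band = 1.96 / np.sqrt(76 - 3)
        assert abs(np.arctanh(row["r"]) - np.arctanh(0.6)) <= 2 * band

    def test_group_effect_detected_and_null_stages_quiet(self):
        df = generate_cohort(group_sizes=(13, 53, 10), seed=4)
        rep = analyze_cohort(df)
        anova = rep["differentiation_anova"].set_index("feature")
        # strong planted group separation on the p75 feature
        assert anova.loc["p75", "p"] < 0.05
        assert rep["thresholds"]["bonferroni_pairwise_threshold"] == 0.017
        # stage labels carry no effect; most tests should be quiet
        stage = rep["stage_tests"]
        assert stage["significant"].mean() < 0.5

    def test_identical_groups_rarely_flagged(self):
        # null cohort: differentiation carries no effect either
        flags = []
        for seed in range(10):
            df = generate_cohort(group_sizes=(13, 53, 10), planted_r=0.0,
                                 differentiation_effect=False, seed=100 + seed)
            rep = analyze_cohort(df)
            flags.extend(rep["differentiation_anova"]["significant"].tolist())
        assert np.mean(flags) < 0.2

    def test_missing_label_column_named(self):
        df = generate_cohort(seed=0).drop(columns=["n_status"])
        with pytest.raises(ValueError, match="n_status"):
            analyze_cohort(df)

    def test_single_subject_table_rejected(self):
        df = generate_cohort(seed=0).iloc[:1]
        with pytest.raises(ValueError):
            analyze_cohort(df)

    def test_group_means_reported_with_sd(self):
        df = generate_cohort(seed=1)
        rep = analyze_cohort(df)
        anova = rep["differentiation_anova"]
        for col in ("mean_good", "sd_good", "mean_moderate", "sd_moderate",
                    "mean_poor", "sd_poor"):
            assert col in anova.columns
            assert anova[col].notna().all()
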