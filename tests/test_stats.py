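import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from poseactivity.stats import (
    bh_adjust,
    chi2_2x2,
    conners_correlations,
    domain_bonferroni,
    effect_size_r,
    group_differences,
    hanley_mcneil_ci,
    mann_whitney,
    pooled_t_from_summary,
    shapiro_gate,
    spearman_ci,
    spearman_matrix,
    u_from_mean_ranks,
    wilson_interval,
)

SEEDED = settings(max_examples=30, deadline=None, derandomize=True)


def brute_force_u(a, b):
    """Pairwise win count: pairs where a < b, ties half-credited, min side."""
    a, b = np.asarray(a), np.asarray(b)
    wins_a = sum((x < y) + 0.5 * (x == y) for x in a for y in b)
    wins_b = len(a) * len(b) - wins_a
    return min(wins_a, wins_b)


class TestMannWhitney:
    def test_identical_multisets_symmetric(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = mann_whitney(a, a.copy())
        assert res.u == len(a) ** 2 / 2
        assert res.z == 0.0
        assert res.p_raw == 1.0
        assert res.direction == "n.s."

    def test_complete_separation(self):
        res = mann_whitney([10.0, 11.0, 12.0], [1.0, 2.0, 3.0, 4.0])
        assert res.u == 0.0
        assert res.direction == "risk>control"

    @given(st.integers(0, 2**31 - 1))
    @SEEDED
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 8, size=20).astype(float)  # many ties
        b = rng.integers(0, 8, size=31).astype(float)
        res = mann_whitney(a, b)
        assert res.u == pytest.approx(brute_force_u(a, b))

    def test_p_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 31)
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-10)


class TestEffectSizeAndMeanRanks:
    @pytest.mark.parametrize("u,expected_r", [(182.0, 0.346), (160.0, 0.405)])
    def test_effect_size_from_u_no_ties(self, u, expected_r):
        """r = |Z|/sqrt(N) with the no-tie normal approximation, n=20/31."""
        n1, n2 = 20, 31
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert effect_size_r(z, n1 + n2) == pytest.approx(expected_r, abs=5e-4)

    def test_zero_z_zero_r(self):
        assert effect_size_r(0.0, 51) == 0.0

    def test_u_from_printed_mean_ranks(self):
        """Mean ranks 33.75 (n=20) vs 21.00 (n=31) recover U = 155."""
        assert u_from_mean_ranks(33.75, 20, 21.00, 31) == 155.0

    def test_u_from_equal_mean_ranks_is_half_max(self):
        n1, n2 = 10, 14
        mr = (n1 + n2 + 1) / 2
        assert u_from_mean_ranks(mr, n1, mr, n2) == n1 * n2 / 2

    def test_inconsistent_mean_ranks_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            u_from_mean_ranks(40.0, 20, 30.0, 31)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        res = spearman_ci(x, x**3)
        assert res.rho == pytest.approx(1.0)

    def test_matches_rank_then_pearson_with_ties(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        res = spearman_ci(x, y)
        expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 25))
        res = spearman_ci(x, y)
        assert res.ci_low <= res.rho <= res.ci_high

    def test_ci_coverage_under_null(self):
        """Fisher-z CI covers rho=0 about 95% of the time under independence."""
        rng = np.random.default_rng(31)
        n_cover = 0
        reps = 400
        for _ in range(reps):
            x, y = rng.normal(size=(2, 30))
            res = spearman_ci(x, y)
            n_cover += res.ci_low <= 0 <= res.ci_high
        assert n_cover / reps == pytest.approx(0.95, abs=0.04)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_ci(np.ones(10), np.arange(10.0))


def brute_force_bh(p):
    """Step-up definition: adj_i = min over j>=i (sorted) of m*p_(j)/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2] * 6)
        np.testing.assert_allclose(out, 0.2)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @SEEDED
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_sorted_order_and_dominates_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestDomainBonferroni:
    def test_limb_domain_threshold(self):
        p = {"right_shoulder": 0.01, "right_elbow": 0.02,
             "right_wrist": 0.012, "right_hand": 0.2}
        (corr,) = domain_bonferroni(p)
        assert corr.alpha_adj == 0.0125
        assert corr.outcomes == {"right_shoulder": True, "right_elbow": False,
                                 "right_wrist": True, "right_hand": False}

    def test_head_domain_uncorrected(self):
        (corr,) = domain_bonferroni({"head": 0.04})
        assert corr.m == 1 and corr.alpha_adj == 0.05
        assert corr.outcomes["head"]

    def test_boundary_p_not_significant(self):
        (corr,) = domain_bonferroni({"left_hip": 0.0125, "left_knee": 0.5,
                                     "left_ankle": 0.5, "left_foot": 0.5})
        assert corr.outcomes["left_hip"] is False

    def test_unassigned_outcome_rejected(self):
        with pytest.raises(ValueError, match="no domain"):
            domain_bonferroni({"sternum": 0.01})


class TestSummaryTests:
    def test_age_row_from_summary_stats(self):
        """Group means 52.58 (sd 3.40, n=31) vs 52.75 (sd 3.95, n=20)."""
        t, df, p = pooled_t_from_summary(52.58, 3.40, 31, 52.75, 3.95, 20)
        assert t == pytest.approx(-0.16, abs=5e-3)
        assert df == 49
        assert p == pytest.approx(0.87, abs=5e-3)

    def test_equal_means_t_zero(self):
        t, _, p = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == 1.0

    def test_matches_long_form_on_constructed_vectors(self):
        def vec(mean, sd, n, seed):
            rng = np.random.default_rng(seed)
            v = rng.normal(size=n)
            v = (v - v.mean()) / v.std(ddof=1)
            return v * sd + mean

        a, b = vec(3.0, 1.2, 14, 0), vec(2.4, 0.9, 18, 1)
        t, df, p = pooled_t_from_summary(3.0, 1.2, 14, 2.4, 0.9, 18)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_sex_table_chi_square(self):
        """15/16 vs 14/6 boys/girls: chi2(1) = 2.32, p = 0.13."""
        chi2, df, p = chi2_2x2(np.array([[15, 16], [14, 6]]))
        assert chi2 == pytest.approx(2.32, abs=5e-3)
        assert df == 1
        assert p == pytest.approx(0.13, abs=5e-3)

    def test_chi2_identical_proportions_zero(self):
        chi2, _, p = chi2_2x2(np.array([[10, 20], [5, 10]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi2_matches_direct_formula_and_scipy(self):
        obs = np.array([[7, 12], [13, 4]])
        chi2, _, p = chi2_2x2(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        direct = ((obs - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(direct)
        ref = sps.chi2_contingency(obs, correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_2x2(np.array([[0, 0], [5, 10]]))


class TestIntervals:
    @pytest.mark.parametrize(
        "k,n,low,high",
        [(36, 51, 0.570, 0.813), (30, 51, 0.452, 0.712)],
    )
    def test_wilson_printed_bounds(self, k, n, low, high):
        got = wilson_interval(k, n)
        assert got[0] == pytest.approx(low, abs=5e-4)
        assert got[1] == pytest.approx(high, abs=5e-4)

    def test_wilson_zero_successes(self):
        low, high = wilson_interval(0, 20)
        assert low == 0.0 and 0 < high < 1

    def test_wilson_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 10), (17, 51), (50, 51)]:
            ref = proportion_confint(k, n, method="wilson")
            got = wilson_interval(k, n)
            assert got == pytest.approx(ref, abs=1e-10)

    @given(st.integers(0, 60), st.integers(1, 60))
    @SEEDED
    def test_wilson_contains_estimate_within_unit(self, k, n):
        k = min(k, n)
        low, high = wilson_interval(k, n)
        assert 0 <= low <= k / n <= high <= 1

    @pytest.mark.parametrize(
        "auc,low,high", [(0.76, 0.62, 0.90), (0.42, 0.26, 0.58)]
    )
    def test_hanley_mcneil_printed_bounds(self, auc, low, high):
        got = hanley_mcneil_ci(auc, 20, 31)
        assert got[0] == pytest.approx(low, abs=5e-3)
        assert got[1] == pytest.approx(high, abs=5e-3)

    def test_hanley_mcneil_symmetric_at_half(self):
        low, high = hanley_mcneil_ci(0.5, 15, 15)
        assert low + high == pytest.approx(1.0)
        assert low <= 0.5 <= high


class TestGateAndTables:
    def test_shapiro_gate_decisions(self):
        rng = np.random.default_rng(6)
        gaussian = {"a": rng.normal(size=200), "b": rng.normal(size=200)}
        assert shapiro_gate(gaussian) == "parametric"
        skewed = {"a": rng.normal(size=200), "b": np.exp(rng.normal(size=200) * 2)}
        assert shapiro_gate(skewed) == "nonparametric"
        # deterministic given data
        assert shapiro_gate(skewed) == "nonparametric"

    def test_group_differences_table_layout(self, feature_cohort):
        table = group_differences(feature_cohort)
        assert len(table) == 15
        assert not any("hip" in r for r in table["region"])
        assert table["p_raw"].between(0, 1).all()
        assert (table["U"] <= 20 * 31 / 2).all()

    def test_spearman_matrix_structure(self, feature_cohort):
        mat = spearman_matrix(feature_cohort)
        assert mat.shape == (15, 15)
        np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat.values), 1.0)

    def test_spearman_matrix_duplicated_column(self, feature_cohort):
        doubled = feature_cohort.copy()
        doubled["left_ankle"] = doubled["right_ankle"]
        mat = spearman_matrix(doubled)
        assert mat.loc["left_ankle", "right_ankle"] == pytest.approx(1.0)

    def test_conners_correlations_positive_for_distal(self, feature_cohort):
        corr = conners_correlations(feature_cohort).set_index("region")
        assert (corr["ci_low"] <= corr["rho"]).all()
        assert (corr["rho"] <= corr["ci_high"]).all()
        # teacher rating is coupled to latent activity: distal rho positive
        assert corr.loc["left_ankle", "rho"] > 0
        assert corr.loc["right_hand", "rho"] > 0
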