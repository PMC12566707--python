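"""Theil-Sen, Mann-Kendall, Kruskal-Wallis/Dunn and BH-FDR."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phyloresist import (
    DegenerateInputError,
    ValidationError,
    bh_fdr,
    kruskal_dunn,
    mann_kendall,
    theil_sen,
)


def pairwise_slope_median(x, y):
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i, j in itertools.combinations(range(len(x)), 2)
        if x[j] != x[i]
    ]
    return np.median(slopes)


class TestTheilSen:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = theil_sen(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_response(self):
        res = theil_sen([0, 1, 2, 3], [5, 5, 5, 5])
        assert res.slope == 0.0

    def test_all_x_identical_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            theil_sen([2, 2, 2], [1, 2, 3])

    @pytest.mark.parametrize(
        "x,y",
        [
            ((0, 1, 2, 3), (0, 0, 0, 10)),
            ((0, 1, 2, 3, 4), (1, 5, 2, 8, 3)),
            ((0.0, 0.3, 0.3, 0.7, 1.0), (4, 3, 5, 2, 1)),
        ],
    )
    def test_matches_exhaustive_pairwise_median(self, x, y):
        res = theil_sen(np.array(x, float), np.array(y, float))
        assert res.slope == pytest.approx(pairwise_slope_median(x, y))

    def test_intercept_is_median_of_residuals(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = 3 * x + rng.normal(size=15)
        res = theil_sen(x, y)
        assert res.intercept == pytest.approx(np.median(y - res.slope * x))

    def test_single_outlier_robustness(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        y[7] = 1000.0
        assert theil_sen(x, y).slope == pytest.approx(2.0, abs=0.2)


class TestMannKendall:
    def test_perfect_concordance(self):
        x = np.arange(8.0)
        res = mann_kendall(x, x**3)
        assert res.tau == pytest.approx(1.0)
        assert res.s_statistic == 8 * 7 // 2

    def test_reversal_flips_tau_and_s(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        a = mann_kendall(x, y)
        b = mann_kendall(x, -y)
        assert b.tau == pytest.approx(-a.tau)
        assert b.s_statistic == -a.s_statistic
        assert b.p_value == pytest.approx(a.p_value)

    def test_exact_p_equals_permutation_enumeration(self):
        x = np.arange(6.0)
        y = np.array([2.0, 0.0, 4.0, 1.0, 5.0, 3.0])
        res = mann_kendall(x, y)
        assert res.method == "exact"
        s_obs = res.s_statistic
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            s = sum(
                np.sign(perm[j] - perm[i])
                for i, j in itertools.combinations(range(6), 2)
            )
            total += 1
            if abs(s) >= abs(s_obs):
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_null_s_distribution_is_symmetric(self):
        # enumeration of all n=5 permutations: S symmetric around 0
        svals = []
        for perm in itertools.permutations(range(5)):
            svals.append(
                sum(
                    np.sign(perm[j] - perm[i])
                    for i, j in itertools.combinations(range(5), 2)
                )
            )
        svals = np.array(svals)
        assert svals.mean() == 0
        assert np.array_equal(np.sort(svals), np.sort(-svals))

    def test_tie_corrected_p_close_to_scipy(self):
        # stage-replicated gradient: heavy ties in x
        x = np.repeat([0.0, 0.3, 0.7, 1.0], 4)
        rng = np.random.default_rng(5)
        y = 2 * x + rng.normal(size=16)
        res = mann_kendall(x, y)
        ref = stats.kendalltau(x, y)
        assert res.tau == pytest.approx(ref.statistic)
        # continuity correction makes ours slightly conservative
        assert res.p_value == pytest.approx(ref.pvalue, abs=0.02)

    def test_n_below_three_rejected(self):
        with pytest.raises(ValidationError):
            mann_kendall([0, 1], [1, 2])

    @given(
        st.lists(
            st.integers(min_value=-100, max_value=100),
            min_size=4,
            max_size=12,
            unique=True,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_tau_invariant_under_monotone_transforms(self, y):
        x = np.arange(len(y), dtype=float)
        y = np.array(y, dtype=float)
        base = mann_kendall(x, y)
        assert mann_kendall(np.exp(x / 10), y).tau == pytest.approx(base.tau)
        assert mann_kendall(x, np.arctan(y / 50)).tau == pytest.approx(base.tau)


class TestKruskalDunn:
    def test_identical_values_h_zero_p_one(self):
        res = kruskal_dunn({"a": [3, 3], "b": [3, 3, 3]})
        assert res.kw_statistic == 0.0
        assert res.kw_p == 1.0

    def test_h_matches_hand_rank_formula(self):
        groups = {"g1": [1, 2, 3], "g2": [10, 20, 30], "g3": [100, 200, 300]}
        res = kruskal_dunn(groups)
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        n = 9
        rbars = {"g1": 2.0, "g2": 5.0, "g3": 8.0}
        h = 12.0 / (n * (n + 1)) * sum(3 * (rbars[g] - 5.0) ** 2 for g in groups)
        assert res.kw_statistic == pytest.approx(h)

    def test_dunn_z_hand_computed_two_groups(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        res = kruskal_dunn(groups)
        (a, b, z, p, padj) = res.pairwise[0]
        n = 6
        se = math.sqrt(n * (n + 1) / 12.0 * (1 / 3 + 1 / 3))
        assert z == pytest.approx((2.0 - 5.0) / se)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_pair_count_is_k_choose_2(self):
        groups = {s: [i, i + 1] for i, s in enumerate(["BF", "LM", "HM", "MB"])}
        res = kruskal_dunn(groups)
        assert len(res.pairwise) == 6

    def test_letters_separate_clearly_different_groups(self):
        rng = np.random.default_rng(0)
        groups = {
            "lo": list(rng.normal(0, 0.1, 8)),
            "hi": list(rng.normal(100, 0.1, 8)),
        }
        res = kruskal_dunn(groups)
        assert res.letters["lo"] != res.letters["hi"]

    def test_letters_shared_for_identical_groups(self):
        groups = {"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]}
        res = kruskal_dunn(groups)
        assert res.letters["a"] == res.letters["b"]


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20)
    )
    @settings(max_examples=50, deadline=None)
    def test_never_decreases_and_matches_step_up_oracle(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # independent step-up construction
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(ranked, 1.0)
        np.testing.assert_allclose(adj, oracle, atol=1e-12)
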