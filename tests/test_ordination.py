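"""RDA, VIF and variance partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phyloresist import RDA, ValidationError, adjusted_r2, variance_partition, vif


def random_data(seed=0, n=16, p=3, m=2, signal=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    B = rng.normal(size=(m, p))
    Y = signal * X @ B + rng.normal(size=(n, p))
    return Y, X


class TestRdaCore:
    def test_noiseless_linear_response(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 2))
        b = rng.normal(size=(2, 1))
        Y = np.hstack([X @ b, 2 * X @ b, -X @ b])  # rank-1 response
        res = RDA(Y, X).fit(n_permutations=99, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.explained_fraction_per_axis[0] == pytest.approx(100.0, abs=1e-6)

    def test_single_pair_r2_is_squared_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = 0.6 * x + rng.normal(size=20)
        res = RDA(y[:, None], x[:, None]).fit(n_permutations=99, seed=0)
        assert res.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_adjusted_r2_is_ezekiel_closed_form(self):
        Y, X = random_data(3)
        res = RDA(Y, X).fit(n_permutations=99, seed=0)
        n, m = X.shape
        assert res.r2_adjusted == pytest.approx(
            1 - (1 - res.r2) * (n - 1) / (n - m - 1)
        )
        assert res.r2_adjusted <= res.r2

    def test_row_shuffle_invariance(self):
        Y, X = random_data(4)
        res = RDA(Y, X).fit(n_permutations=199, seed=7)
        perm = np.random.default_rng(0).permutation(Y.shape[0])
        res2 = RDA(Y[perm], X[perm]).fit(n_permutations=199, seed=7)
        assert res2.r2 == pytest.approx(res.r2)
        np.testing.assert_allclose(res2.eigenvalues, res.eigenvalues, rtol=1e-9)

    def test_strong_signal_is_significant(self):
        Y, X = random_data(5, signal=3.0)
        res = RDA(Y, X).fit(n_permutations=199, seed=1)
        assert res.global_p < 0.05
        assert res.r2 > 0.5

    def test_rank_deficient_predictors_named(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=16)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=16)})
        with pytest.raises(ValidationError, match="a.*b|b.*a"):
            RDA(rng.normal(size=(16, 2)), X)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            RDA(np.zeros((4, 2)) + np.random.default_rng(0).normal(size=(4, 2)),
                np.random.default_rng(1).normal(size=(4, 4)))

    def test_axis_fractions_sum_to_100(self):
        Y, X = random_data(8, p=4, m=3)
        res = RDA(Y, X).fit(n_permutations=99, seed=0)
        assert res.explained_fraction_per_axis.sum() == pytest.approx(100.0)

    def test_matches_vegan_rda_reference(self):
        # frozen oracle: vegan::rda(Y ~ ., data=X) on this exact dataset
        # gives constrained eigenvalues 4.308857, 0.630433, R^2 0.6399935
        # and adjusted R^2 0.5976398
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 2))
        B = rng.normal(size=(2, 3))
        Y = X @ B + rng.normal(size=(20, 3))
        res = RDA(Y, X, scale=False).fit(n_permutations=99, seed=0)
        np.testing.assert_allclose(res.eigenvalues, [4.308857, 0.630433], rtol=1e-5)
        assert res.r2 == pytest.approx(0.6399935, rel=1e-6)
        assert res.r2_adjusted == pytest.approx(0.5976398, rel=1e-6)

    def test_summary_reports_key_quantities(self):
        Y, X = random_data(10)
        text = RDA(Y, X).fit(n_permutations=99, seed=0).summary()
        assert "adjusted R^2" in text and "VIF" in text


class TestPermutationCalibration:
    def test_null_rejection_rate_near_alpha(self):
        # Y independent of X: global permutation p should be ~uniform
        rng = np.random.default_rng(20251021)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            Y = rng.normal(size=(16, 2))
            X = rng.normal(size=(16, 2))
            res = RDA(Y, X).fit(n_permutations=99, seed=int(rng.integers(2**31)))
            if res.global_p <= 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.04)


class TestVif:
    def test_orthogonal_predictors_vif_one(self):
        # zero-mean, mutually orthogonal contrast columns
        X = np.array(
            [
                [1, 1, 1],
                [1, -1, -1],
                [-1, 1, -1],
                [-1, -1, 1],
            ] * 2,
            dtype=float,
        )
        out = vif(X)
        for v in out.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_infinite(self):
        x = np.random.default_rng(0).normal(size=10)
        out = vif(np.column_stack([x, x, np.random.default_rng(1).normal(size=10)]))
        assert np.isinf(out["x0"]) and np.isinf(out["x1"])

    def test_correlated_pair_closed_form(self):
        # construct exactly correlated pair with r = 0.9
        rng = np.random.default_rng(3)
        n = 2000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        out = vif(np.column_stack([a, b]))
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        for v in out.values():
            assert v == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)


class TestVpa:
    def test_additive_identity_on_random_data(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            Y = rng.normal(size=(16, 3))
            cover = rng.normal(size=(16, 1))
            soil = rng.normal(size=(16, 3))
            f = variance_partition(Y, cover, soil)
            total = f.unique_cover + f.unique_soil + f.shared + f.unexplained
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_shared_dominates_when_soil_mediates_cover(self):
        rng = np.random.default_rng(42)
        cover = np.linspace(0, 1, 16)[:, None]
        soil = np.hstack([2 * cover, -1.5 * cover, 0.5 * cover]) + rng.normal(
            0, 0.05, size=(16, 3)
        )
        Y = soil @ rng.normal(size=(3, 3)) + rng.normal(0, 0.3, size=(16, 3))
        f = variance_partition(Y, cover, soil)
        assert f.shared > f.unique_cover
        assert f.shared > f.unique_soil

    def test_orthogonal_design_has_no_shared_fraction(self):
        rng = np.random.default_rng(43)
        n = 40
        cover = rng.normal(size=(n, 1))
        soil = rng.normal(size=(n, 2))
        soil -= cover @ np.linalg.lstsq(cover, soil, rcond=None)[0]  # orthogonalize
        Y = 2 * cover @ np.ones((1, 2)) + rng.normal(0, 0.5, size=(n, 2))
        f = variance_partition(Y, cover, soil)
        assert f.unique_cover > 0.5
        assert abs(f.shared) < 0.1
        assert f.unique_cover > f.unique_soil

    def test_pure_noise_mostly_unexplained(self):
        rng = np.random.default_rng(44)
        f = variance_partition(
            rng.normal(size=(30, 3)), rng.normal(size=(30, 1)), rng.normal(size=(30, 3))
        )
        assert f.unexplained > 0.8

    def test_clamped_and_normalized_views(self):
        rng = np.random.default_rng(45)
        f = variance_partition(
            rng.normal(size=(16, 3)), rng.normal(size=(16, 1)), rng.normal(size=(16, 3))
        )
        c = f.clamped()
        assert min(c.values()) >= 0.0
        oe = f.of_explained()
        if sum(oe.values()) > 0:
            assert sum(oe.values()) == pytest.approx(1.0)
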