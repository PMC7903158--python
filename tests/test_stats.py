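"""Behavior transforms, permutation tests, circular statistics."""

import numpy as np
import pingouin
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import alpharhythm as ar
from alpharhythm.errors import ConfigurationError, DataError
from alpharhythm.stats import bootstrap_ci_mean, sign_flip_pvalues


class TestLogitAdj:
    def test_symmetry_point_and_boundary(self):
        assert ar.logit_adj(0.5) == pytest.approx(0.0)
        assert ar.logit_adj(1.0) == pytest.approx(np.log(0.975 / 0.025), abs=1e-12)
        assert ar.logit_adj(1.0) == pytest.approx(3.6636, abs=1e-4)

    @given(st.floats(0.0, 1.0))
    def test_odd_about_half_and_monotone(self, x):
        assert ar.logit_adj(x) == pytest.approx(-ar.logit_adj(1 - x), abs=1e-10)
        if x < 1.0:
            assert ar.logit_adj(x) < ar.logit_adj(min(1.0, x + 1e-3))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            ar.logit_adj(1.1)


class TestResponseSpeed:
    def test_cutoff_exclusion(self):
        np.testing.assert_allclose(ar.response_speed([0.5, 4.0], cutoff=3.0), [2.0])

    def test_all_kept_when_below_cutoff(self):
        out = ar.response_speed([0.5, 1.0, 2.9])
        assert out.size == 3

    def test_matches_brute_force_reciprocals(self):
        rng = np.random.default_rng(0)
        rts = rng.lognormal(0.0, 0.4, 500)
        kept = rts[rts <= 3.0]
        assert ar.response_speed(rts).mean() == pytest.approx((1 / kept).mean())

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(DataError):
            ar.response_speed([1.0, -0.2])

    def test_empty_cell_warns(self):
        with pytest.warns(UserWarning, match="cutoff"):
            out = ar.response_speed([4.0, 5.0])
        assert out.size == 0


class TestPermTTest:
    def test_identical_samples_give_p_one(self):
        a = np.array([0.3, 0.5, 0.7, 0.2])
        t, p = ar.perm_ttest_paired(a, a, n_perm=100, seed=0)
        assert (t, p) == (0.0, 1.0)

    def test_exhaustive_enumeration_of_constant_differences(self):
        # all 2^3 sign flips; |t| infinite only for the two all-same patterns
        t, p = ar.perm_ttest_paired(np.array([1.0, 1.0, 1.0]), n_perm=10000, seed=0)
        assert np.isinf(t)
        assert p == pytest.approx(2 / 8)

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal(6)
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        count = 0
        for code in range(2**6):
            signs = np.array([1 if code >> i & 1 else -1 for i in range(6)])
            sd = signs * d
            t = sd.mean() / (sd.std(ddof=1) / np.sqrt(6))
            count += abs(t) >= abs(t_obs) - 1e-10
        _, p = ar.perm_ttest_paired(d, n_perm=10**6, seed=0)
        assert p == pytest.approx(count / 2**6)

    @given(seed=st.integers(0, 2**16))
    def test_two_sided_symmetry_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(8)
        b = rng.standard_normal(8)
        _, p_ab = ar.perm_ttest_paired(a, b, n_perm=512, seed=3)
        _, p_ba = ar.perm_ttest_paired(b, a, n_perm=512, seed=3)
        assert p_ab == pytest.approx(p_ba)
        assert 0 < p_ab <= 1

    def test_invalid_n_perm(self):
        with pytest.raises(ConfigurationError):
            ar.perm_ttest_paired(np.arange(4.0), n_perm=0)


class TestSignFlipSeries:
    def test_shared_positive_point_matches_enumeration(self):
        z = np.zeros((5, 3))
        z[:, 1] = 2.0  # all participants agree at one time point
        p = sign_flip_pvalues(z, n_perm=10000, seed=0)
        assert p[1] == pytest.approx(2 / 2**5)
        assert p[0] == 1.0 and p[2] == 1.0

    def test_matches_scalar_test_per_column(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((7, 4))
        p_cols = sign_flip_pvalues(z, n_perm=10000, seed=0)
        for j in range(4):
            _, p = ar.perm_ttest_paired(z[:, j], n_perm=10000, seed=5)
            assert p_cols[j] == pytest.approx(p, abs=1e-12)


class TestPermSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, p = ar.perm_spearman(x, np.exp(x), n_perm=500, seed=0)
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_reversal_gives_minus_one(self):
        x = np.arange(8.0)
        rho, _ = ar.perm_spearman(x, x[::-1], n_perm=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_rho_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 25))
        rho, _ = ar.perm_spearman(x, y, n_perm=10, seed=0)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(300):
            x, y = rng.uniform(size=(2, 15))
            _, p = ar.perm_spearman(x, y, n_perm=200, seed=rng.integers(2**31))
            ps.append(p)
        ps = np.asarray(ps)
        assert abs(ps.mean() - 0.5) < 0.06
        assert abs((ps < 0.05).mean() - 0.05) < 0.035

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError):
            ar.perm_spearman(np.ones(5), np.arange(5.0))


class TestRayleigh:
    def test_identical_angles(self):
        z, p = ar.rayleigh_test(np.full(20, 1.2))
        assert z == pytest.approx(20.0)
        assert p < 1e-6

    def test_balanced_angles_cancel(self):
        z, p = ar.rayleigh_test(np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=0.05)

    @given(rot=st.floats(-np.pi, np.pi), seed=st.integers(0, 2**16))
    def test_rotation_invariance(self, rot, seed):
        rng = np.random.default_rng(seed)
        angles = rng.uniform(-np.pi, np.pi, 15)
        z0, p0 = ar.rayleigh_test(angles)
        z1, p1 = ar.rayleigh_test(angles + rot)
        assert z0 == pytest.approx(z1, abs=1e-9)
        assert p0 == pytest.approx(p1, abs=1e-9)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            angles = rng.vonmises(0.0, rng.uniform(0, 2), 24)
            z, p = ar.rayleigh_test(angles)
            z_ref, p_ref = pingouin.circ_rayleigh(angles)
            assert z == pytest.approx(z_ref, rel=1e-9)
            assert p == pytest.approx(p_ref, rel=1e-6)


class TestHotellingPaired:
    def test_identical_samples_are_boundary_case(self):
        a = np.random.default_rng(0).uniform(-np.pi, np.pi, 10)
        F, p = ar.hotelling_paired_circular(a, a.copy())
        assert F == 0.0 and p == 1.0

    def test_antipodal_shift_strongly_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.vonmises(0.5, 4.0, 20)
        b = (a + np.pi + rng.normal(0, 0.2, 20) + np.pi) % (2 * np.pi) - np.pi
        F, p = ar.hotelling_paired_circular(a, b)
        assert p < 1e-4

    def test_type_one_error_close_to_alpha_under_null(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 400
        for _ in range(reps):
            common = rng.vonmises(0.0, 1.5, 15)
            a = common + rng.normal(0, 0.5, 15)
            b = common + rng.normal(0, 0.5, 15)
            _, p = ar.hotelling_paired_circular(a, b)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01


class TestLinearTrend:
    def test_flat_matrix_gives_p_one(self):
        slope, p = ar.linear_trend_test(np.full((6, 5), 0.3), n_perm=100, seed=0)
        assert slope == 0.0 and p == 1.0

    def test_deterministic_unit_slopes(self):
        vals = np.tile(np.arange(1.0, 6.0), (6, 1))
        slope, p = ar.linear_trend_test(vals, n_perm=10000, seed=0)
        assert slope == pytest.approx(1.0)
        assert p == pytest.approx(2 / 2**6)  # exhaustive sign-flip minimum

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(7)
        n, k, true_slope = 20, 5, 0.1
        vals = true_slope * np.arange(1, k + 1) + rng.normal(0, 0.05, (n, k))
        slope, p = ar.linear_trend_test(vals, n_perm=2000, seed=1)
        assert slope == pytest.approx(true_slope, abs=0.03)
        assert p < 0.05

    def test_missing_cells_drop_participants_with_warning(self):
        vals = np.tile(np.arange(1.0, 5.0), (4, 1))
        vals[0, 2] = np.nan
        with pytest.warns(UserWarning, match="dropping"):
            slope, _ = ar.linear_trend_test(vals, n_perm=100, seed=0)
        assert slope == pytest.approx(1.0)


class TestBootstrapCI:
    def test_interval_brackets_mean_and_narrows(self):
        rng = np.random.default_rng(9)
        x = rng.normal(2.0, 1.0, 200)
        lo, hi = bootstrap_ci_mean(x, n_boot=2000, seed=0)
        assert lo < x.mean() < hi
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert (hi - lo) == pytest.approx(2 * 1.96 * se, rel=0.2)

    def test_columnwise_shapes(self):
        x = np.random.default_rng(1).normal(size=(30, 4))
        lo, hi = bootstrap_ci_mean(x, n_boot=500, seed=0)
        assert lo.shape == hi.shape == (4,)
        assert np.all(lo <= hi)
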