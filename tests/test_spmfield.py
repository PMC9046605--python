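import numpy as np
import pytest
from scipy import stats

from stancelab.errors import DataError, ParameterError, SampleSizeError
from stancelab.spmfield import (estimate_fwhm, f_field, f_fields_twoway,
                                hotelling_t2_field, permutation_threshold,
                                rft_threshold, sidak_alpha,
                                smooth_gaussian_fields, spm_test,
                                suprathreshold_clusters, t_field)


class TestTField:
    def test_identical_groups_zero_field(self, rng):
        a = rng.standard_normal((8, 101))
        field, dof = t_field(a, a.copy())
        assert np.allclose(field, 0.0)
        assert dof == (14,)

    def test_constant_trajectories_equal_scalar_t(self, rng):
        xa = rng.standard_normal(10)
        xb = rng.standard_normal(12) + 0.5
        a = np.tile(xa[:, None], (1, 101))
        b = np.tile(xb[:, None], (1, 101))
        field, _ = t_field(a, b)
        want = stats.ttest_ind(xa, xb, equal_var=True).statistic
        assert np.allclose(field, want, atol=1e-10)

    def test_paired_matches_scalar_paired_t(self, rng):
        a = rng.standard_normal((9, 101))
        b = rng.standard_normal((9, 101))
        field, dof = t_field(a, b, paired=True)
        want = stats.ttest_rel(a, b, axis=0).statistic
        assert np.allclose(field, want, atol=1e-10)
        assert dof == (8,)

    def test_minimum_sample_size(self, rng):
        with pytest.raises(SampleSizeError):
            t_field(rng.standard_normal((2, 101)), rng.standard_normal((5, 101)))


class TestFField:
    def test_two_level_f_is_t_squared(self, rng):
        a = rng.standard_normal((7, 101))
        b = rng.standard_normal((9, 101)) + 0.3
        F, _ = f_field([a, b])
        t, _ = t_field(a, b)
        assert np.allclose(F, t ** 2, atol=1e-9)

    def test_all_equal_data_zero_field(self):
        a = np.ones((5, 101))
        b = np.ones((5, 101))
        F, _ = f_field([a, b])
        assert np.allclose(np.nan_to_num(F), 0.0)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.standard_normal((6, 101)) + d for d in (0.0, 0.4, -0.2)]
        F, dof = f_field(groups)
        want = stats.f_oneway(*groups, axis=0).statistic
        assert np.allclose(F, want, atol=1e-10)
        assert dof == (2, 15)

    def test_twoway_interaction_reduces_to_cell_contrast(self, rng):
        cells = {(g, t): rng.standard_normal((6, 101))
                 for g in ("A", "B") for t in ("1", "2")}
        out = f_fields_twoway(cells)
        assert set(out) == {"group", "time", "interaction"}
        F, dof = out["interaction"]
        assert dof == (1, 20)
        assert np.all(F >= -1e-12)


class TestHotelling:
    def test_identical_groups_zero_field(self, rng):
        a = rng.standard_normal((8, 101, 3))
        f, dof = hotelling_t2_field(a, a.copy())
        assert np.allclose(f, 0.0, atol=1e-9)
        assert dof == (3, 14)

    def test_single_component_reduces_to_t_squared(self, rng):
        a = rng.standard_normal((10, 101))
        b = rng.standard_normal((10, 101)) + 0.4
        f2, _ = hotelling_t2_field(a[:, :, None], b[:, :, None])
        t, _ = t_field(a, b)
        assert np.allclose(f2, t ** 2, atol=1e-9)

    def test_constant_vectors_match_classic_hotelling(self, rng):
        # multivariate observations repeated over nodes = the textbook T2
        xa = rng.standard_normal((12, 3))
        xb = rng.standard_normal((10, 3)) + 0.3
        a = np.repeat(xa[:, None, :], 101, axis=1)
        b = np.repeat(xb[:, None, :], 101, axis=1)
        f2, _ = hotelling_t2_field(a, b)
        n1, n2 = 12, 10
        d = xa.mean(0) - xb.mean(0)
        W = ((n1 - 1) * np.cov(xa.T) + (n2 - 1) * np.cov(xb.T)) / (n1 + n2 - 2)
        want = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(W, d)
        assert np.allclose(f2, want, atol=1e-9)

    def test_paired_form(self, rng):
        a = rng.standard_normal((9, 101, 2))
        b = rng.standard_normal((9, 101, 2))
        f2, dof = hotelling_t2_field(a, b, paired=True)
        assert dof == (2, 8)
        d = (a - b)[:, 50, :]
        S = np.cov(d.T)
        want = 9 * d.mean(0) @ np.linalg.solve(S, d.mean(0))
        assert f2[50] == pytest.approx(want, abs=1e-9)

    def test_invariance_to_common_linear_map(self, rng):
        a = rng.standard_normal((10, 101, 3))
        b = rng.standard_normal((11, 101, 3)) + 0.2
        A = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        f2, _ = hotelling_t2_field(a, b)
        g2, _ = hotelling_t2_field(a @ A.T, b @ A.T)
        assert np.allclose(f2, g2, rtol=1e-8)

    def test_singular_covariance_warns(self):
        a = np.zeros((6, 5, 2))
        b = np.zeros((6, 5, 2))
        a[:, :, 0] = np.arange(6)[:, None]
        a[:, :, 1] = 2 * a[:, :, 0]   # perfectly collinear components
        with pytest.warns(UserWarning, match="singular"):
            hotelling_t2_field(a, b)


class TestSmoothness:
    def test_white_noise_fwhm_small(self, rng):
        assert estimate_fwhm(rng.standard_normal((20, 101))) < 3.0

    def test_known_kernel_fwhm_recovered(self, rng):
        est = [estimate_fwhm(smooth_gaussian_fields(rng, 10, 101, 20.0))
               for _ in range(200)]
        assert np.mean(est) == pytest.approx(20.0, abs=2.0)

    def test_scale_invariance(self, rng):
        r = rng.standard_normal((12, 101))
        assert estimate_fwhm(10.0 * r) == pytest.approx(estimate_fwhm(r), rel=1e-12)

    def test_zero_variance_nodes_excluded(self, rng):
        r = rng.standard_normal((10, 50))
        r[:, 7] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            estimate_fwhm(r)


class TestRFTThreshold:
    def test_large_fwhm_limit_is_pointwise_quantile(self):
        u = rft_threshold("t", (20,), 101, 1e9, alpha=0.05, two_sided=True)
        assert u == pytest.approx(stats.t.ppf(0.975, 20), abs=1e-4)

    def test_small_fwhm_between_pointwise_and_bonferroni(self):
        u = rft_threshold("t", (20,), 101, 1.0, alpha=0.05, two_sided=True)
        lo = stats.t.ppf(0.975, 20)
        hi = stats.t.ppf(1 - 0.025 / 101, 20)
        assert lo < u <= hi * 1.05

    def test_threshold_increases_with_resels(self):
        u1 = rft_threshold("t", (20,), 101, 30.0)
        u2 = rft_threshold("t", (20,), 101, 10.0)
        assert u2 > u1

    def test_f_threshold_consistent_with_two_sided_t(self):
        # an F(1, nu) field is the square of a t(nu) field
        ut = rft_threshold("t", (18,), 101, 15.0, alpha=0.05, two_sided=True)
        uf = rft_threshold("F", (1, 18), 101, 15.0, alpha=0.05)
        assert uf == pytest.approx(ut ** 2, rel=1e-4)

    def test_t2_threshold_via_f_transform(self):
        p, nu = 3, 20
        u2 = rft_threshold("T2", (p, nu), 101, 12.0)
        uf = rft_threshold("F", (p, nu - p + 1), 101, 12.0)
        assert u2 == pytest.approx(uf * nu * p / (nu - p + 1), rel=1e-9)

    def test_invalid_alpha(self):
        with pytest.raises(ParameterError):
            rft_threshold("t", (10,), 101, 20.0, alpha=0.7)


class TestClusters:
    def test_subthreshold_field_empty(self):
        assert suprathreshold_clusters(np.zeros(101), 1.0) == []

    def test_single_run_bounds(self):
        f = np.zeros(101)
        f[80:97] = 5.0
        cl = suprathreshold_clusters(f, 2.0)
        assert len(cl) == 1
        assert (cl[0].start_node, cl[0].end_node) == (80, 96)

    def test_two_disjoint_runs_order_preserved(self):
        f = np.zeros(101)
        f[10:20] = 3.0
        f[60:70] = 3.0
        cl = suprathreshold_clusters(f, 1.0)
        assert [(c.start_node, c.end_node) for c in cl] == [(10, 19), (60, 69)]

    def test_cluster_p_monotone_in_extent(self):
        base = np.zeros(101)
        ps = []
        for width in (5, 15, 30):
            f = base.copy()
            f[40:40 + width] = 3.5
            cl = suprathreshold_clusters(f, 3.0, fwhm=15.0, statistic_name="t",
                                         dof=(20,), two_sided=True)
            ps.append(cl[0].p)
        assert ps[0] > ps[1] > ps[2]
        assert all(0.0 < p <= 1.0 for p in ps)

    def test_nonfinite_field_raises(self):
        with pytest.raises(DataError):
            suprathreshold_clusters(np.r_[np.nan, np.zeros(100)], 1.0)


class TestSidak:
    def test_single_comparison_unchanged(self):
        assert sidak_alpha(0.05, 1) == pytest.approx(0.05)

    def test_three_comparisons_closed_form(self):
        assert sidak_alpha(0.05, 3) == pytest.approx(1 - 0.95 ** (1 / 3), abs=1e-12)
        assert sidak_alpha(0.05, 3) == pytest.approx(0.016952, abs=1e-5)

    def test_always_at_least_bonferroni(self):
        for k in (1, 2, 5, 20):
            assert sidak_alpha(0.05, k) >= 0.05 / k


class TestPermutation:
    def test_seed_determinism(self, rng):
        a = rng.standard_normal((8, 51))
        b = rng.standard_normal((8, 51))
        u1 = permutation_threshold((a, b), "t", n_perm=200, seed=5)
        u2 = permutation_threshold((a, b), "t", n_perm=200, seed=5)
        assert u1 == u2

    def test_too_few_permutations_error(self, rng):
        a = rng.standard_normal((2, 51))
        b = rng.standard_normal((2, 51))
        with pytest.raises(ParameterError):
            permutation_threshold((a, b), "t", n_perm=100, seed=0, alpha=0.05)

    def test_paired_sign_flip_threshold_positive(self, rng):
        a = rng.standard_normal((10, 51))
        b = rng.standard_normal((10, 51))
        u = permutation_threshold((a, b), "t_paired", n_perm=200, seed=1)
        assert u > 0


class TestSpmTest:
    def test_wrapper_consistency(self, rng):
        a = smooth_gaussian_fields(rng, 10, 101, 15.0)
        b = smooth_gaussian_fields(rng, 10, 101, 15.0) + 1.5
        res = spm_test(a, b, "t")
        assert res.field.shape == (101,)
        assert res.dof == (18,)
        assert res.fwhm > 3
        for c in res.clusters:
            assert np.all(np.abs(res.field[c.start_node:c.end_node + 1])
                          > res.critical_threshold)

    def test_vector_wrapper(self, rng):
        a = rng.standard_normal((10, 101, 3))
        b = rng.standard_normal((10, 101, 3))
        res = spm_test(a, b, "T2")
        assert res.statistic_name == "T2"
        assert res.dof == (3, 18)
        assert res.critical_threshold > 0
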