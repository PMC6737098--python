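"""Group-difference SPM: moments, Gaussianization, RFT thresholds,
permutation inference and assumption checks."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from retspm.preprocess import SearchRegion, SmoothingSpec, build_search_region
from retspm.spm import (Moments, ThicknessSPM, assumption_checks,
                        ec_expected, groupwise_mean_maps, height_threshold,
                        permutation_test, rft_threshold, z_from_t, z_map)


class TestMoments:
    def test_identical_subjects_zero_sd(self):
        m = groupwise_mean_maps(np.ones((3, 4, 4)), np.ones((2, 4, 4)) * 2)
        assert np.all(m.sd_patient == 0) and np.all(m.sd_control == 0)

    def test_two_value_pixel(self):
        p = np.zeros((2, 1, 1))
        p[0], p[1] = 1.0, 3.0
        m = groupwise_mean_maps(p, np.zeros((2, 1, 1)))
        assert m.mean_patient[0, 0] == pytest.approx(2.0)
        assert m.sd_patient[0, 0] == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_common_mask_requires_all_subjects(self):
        pv = np.ones((2, 4, 4), bool)
        pv[0, 1, 1] = False
        m = groupwise_mean_maps(np.zeros((2, 4, 4)), np.zeros((2, 4, 4)),
                                patient_valid=pv)
        assert not m.valid_mask[1, 1] and m.valid_mask.sum() == 15

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError):
            groupwise_mean_maps(np.ones((1, 4, 4)), np.ones((3, 4, 4)))


class TestZMap:
    def test_equal_means_give_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 3, 3))
        m = groupwise_mean_maps(a, a.copy())
        z, defined = z_map(m)
        np.testing.assert_allclose(z[defined], 0.0, atol=1e-12)

    def test_large_df_limit_z_equals_t(self):
        t = np.array([0.5, 1.0, 2.5, -3.0])
        z = z_from_t(t, df=10 ** 7)
        np.testing.assert_allclose(z, t, atol=1e-3)

    def test_t_to_z_against_quadrature_oracle(self):
        """z = Phi^-1(F_t,41(2.0)) checked against direct high-precision
        quadrature of the t density."""
        import mpmath as mp
        df = 41
        with mp.workdps(40):
            const = mp.gamma((df + 1) / 2) / (mp.sqrt(df * mp.pi) * mp.gamma(df / 2))
            cdf = mp.quad(lambda u: const * (1 + u ** 2 / df) ** (-(df + 1) / 2),
                          [-mp.inf, 2.0])
            expected = mp.sqrt(2) * mp.erfinv(2 * cdf - 1)
        z = z_from_t(np.array([2.0]), df)[0]
        assert z == pytest.approx(float(expected), abs=1e-10)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 6, 6)), rng.normal(size=(7, 6, 6))
        z1, _ = z_map(groupwise_mean_maps(a, b))
        z2, _ = z_map(groupwise_mean_maps(b, a))
        np.testing.assert_allclose(z1, -z2, atol=1e-12)

    def test_zero_variance_pixel_flagged(self):
        a = np.ones((3, 2, 2))
        b = np.ones((3, 2, 2))
        m = groupwise_mean_maps(a, b)
        _, defined = z_map(m)
        assert not defined.any()


class TestRFTThreshold:
    def test_seventeen_resels_threshold(self):
        """Zc for 17 resels at alpha 0.05, area term only, against an
        independent bisection of the EC equation."""
        zc = rft_threshold(17.0, 0.05)

        def ec(z):
            return 17.0 * (4 * math.log(2)) * (2 * math.pi) ** -1.5 \
                * z * math.exp(-z * z / 2)
        lo, hi = 2.0, 5.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if ec(mid) > 0.05:
                lo = mid
            else:
                hi = mid
        assert zc == pytest.approx((lo + hi) / 2, abs=1e-8)
        assert zc == pytest.approx(3.2464, abs=2e-4)

    def test_monotone_in_alpha_and_resels(self):
        assert rft_threshold(17.0, 0.01) > rft_threshold(17.0, 0.05)
        assert rft_threshold(36.0, 0.05) > rft_threshold(17.0, 0.05)

    def test_boundary_terms_raise_threshold(self):
        plain = rft_threshold(9.62, 0.05)
        with_boundary = rft_threshold(9.62, 0.05, resels1=5.5, resels0=1.0)
        assert with_boundary > plain

    def test_ec_probability_decreases_in_height(self):
        zs = np.linspace(2.0, 5.0, 10)
        vals = [ec_expected(z, 17.0) for z in zs]
        assert np.all(np.diff(vals) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rft_threshold(0.0, 0.05)
        with pytest.raises(ValueError):
            rft_threshold(17.0, 1.5)


class TestHeightThreshold:
    def test_zero_map_empty(self):
        region = np.ones((4, 4), bool)
        assert not height_threshold(np.zeros((4, 4)), 3.0, region).any()

    def test_single_supra_threshold_pixel(self):
        z = np.zeros((4, 4))
        z[2, 2] = -3.4
        region = np.ones((4, 4), bool)
        mask = height_threshold(z, 3.3, region, "thinner")
        assert mask[2, 2] and mask.sum() == 1

    def test_outside_region_ignored(self):
        z = np.full((4, 4), -9.0)
        region = np.zeros((4, 4), bool)
        region[0, 0] = True
        assert height_threshold(z, 3.0, region, "thinner").sum() == 1


class TestPermutation:
    def _brute_force(self, maps, region, direction="thinner"):
        """Independent exhaustive enumeration for n1 = n2 = 2."""
        n = 4
        sign = -1.0 if direction == "thinner" else 1.0
        stats_, s_obs = [], None
        for comb in combinations(range(n), 2):
            sel = np.zeros(n, bool)
            sel[list(comb)] = True
            g1, g2 = maps[sel], maps[~sel]
            sp2 = (g1.var(0, ddof=1) + g2.var(0, ddof=1)) / 2.0
            t = (g1.mean(0) - g2.mean(0)) / np.sqrt(sp2)
            s = sign * z_from_t(t, 2)
            stats_.append(s[region].max())
            if comb == (0, 1):
                s_obs = s
        stats_ = np.array(stats_)
        p = np.ones(region.shape)
        p[region] = (stats_[None, :] >= s_obs[region][:, None] - 1e-12).mean(1)
        return p

    def test_exhaustive_two_by_two_matches_enumeration(self):
        rng = np.random.default_rng(5)
        maps = rng.normal(size=(4, 5, 5))
        region = np.ones((5, 5), bool)
        labels = np.array([True, True, False, False])
        p = permutation_test(maps, labels, region, n_perm=1000, seed=0)
        np.testing.assert_array_equal(p, self._brute_force(maps, region))

    def test_min_attainable_p_is_one_over_labelings(self):
        rng = np.random.default_rng(6)
        maps = rng.normal(size=(4, 3, 3)) * 0.01
        maps[:2] -= 50.0  # patients massively thinner everywhere
        labels = np.array([True, True, False, False])
        region = np.ones((3, 3), bool)
        p = permutation_test(maps, labels, region, n_perm=1000, seed=0)
        assert p.min() == pytest.approx(1.0 / 6.0)

    def test_null_p_values_behave_uniformly(self):
        """On exchangeable data, the mid-range of the max-corrected p at
        the most extreme pixel is consistent with its discrete uniform
        null distribution."""
        rng = np.random.default_rng(7)
        mins = []
        labels = np.array([True] * 3 + [False] * 3)
        region = np.ones((2, 2), bool)
        for _ in range(200):
            maps = rng.normal(size=(6, 2, 2))
            p = permutation_test(maps, labels, region, n_perm=20, seed=1)
            mins.append(p.min())
        # the minimum over 4 correlated pixels of an FWE-corrected p is
        # stochastically >= uniform on {1/20,...,1}; its mean must sit in
        # a broad central band
        assert 0.2 < np.mean(mins) < 0.75

    def test_observed_labeling_included(self):
        rng = np.random.default_rng(8)
        maps = rng.normal(size=(10, 2, 2))
        labels = np.array([True] * 5 + [False] * 5)
        region = np.ones((2, 2), bool)
        p = permutation_test(maps, labels, region, n_perm=50, seed=3)
        assert p.min() >= 1.0 / 50.0


class TestAssumptionChecks:
    def test_gaussian_cohort_calibrated(self):
        rng = np.random.default_rng(9)
        p = rng.normal(size=(10, 14, 14))
        c = rng.normal(size=(12, 14, 14))
        region = np.ones((14, 14), bool)
        out = assumption_checks(p, c, region, alpha=0.05)
        # 392 independent Shapiro tests at alpha 0.05: ~0.05 +- binomial
        assert out["normality_fraction"] == pytest.approx(0.05, abs=0.035)
        assert out["variance_fraction"] == pytest.approx(0.05, abs=0.05)

    def test_constant_subjects_degenerate_not_violating(self):
        p = np.ones((3, 3, 3))
        c = np.ones((4, 3, 3)) * 2.0
        out = assumption_checks(p, c, np.ones((3, 3), bool))
        assert out["degenerate"].all()
        assert not out["normality_violation"].any()

    def test_heavy_tails_elevate_violations(self):
        rng = np.random.default_rng(10)
        p = rng.standard_cauchy(size=(12, 10, 10))
        c = rng.normal(size=(12, 10, 10))
        region = np.ones((10, 10), bool)
        out = assumption_checks(p, c, region, alpha=0.05)
        assert out["normality_fraction"] > 0.2


class TestThicknessSPMModel:
    def _region(self, shape=(32, 32)):
        return build_search_region(shape, (6.0, 6.0), SmoothingSpec((1.0, 1.0)),
                                   resel_override=17.0)

    def test_fit_detects_planted_difference(self):
        rng = np.random.default_rng(11)
        region = self._region()
        c = rng.normal(50.0, 1.0, size=(12, 32, 32))
        p = rng.normal(50.0, 1.0, size=(12, 32, 32))
        p[:, 14:18, 14:18] -= 8.0
        res = ThicknessSPM(p, c, region, layer_id="GCL").fit(method="both",
                                                             n_perm=200, seed=0)
        assert res.zc == pytest.approx(3.2464, abs=2e-4)
        assert res.sig_mask[14:18, 14:18].all()
        assert res.perm_sig_mask[14:18, 14:18].all()
        assert "GCL" in res.summary()

    def test_no_difference_usually_quiet(self):
        rng = np.random.default_rng(12)
        region = self._region()
        res = ThicknessSPM(rng.normal(size=(10, 32, 32)),
                           rng.normal(size=(10, 32, 32)), region).fit()
        assert res.n_sig == 0

    def test_sig_mask_confined_to_region(self):
        rng = np.random.default_rng(13)
        region = self._region()
        p = rng.normal(size=(6, 32, 32)) - 30.0   # extreme everywhere
        c = rng.normal(size=(6, 32, 32))
        res = ThicknessSPM(p, c, region).fit()
        assert not (res.sig_mask & ~region.circle_mask).any()
        assert res.sig_mask.any()
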