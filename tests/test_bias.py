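import numpy as np
import pytest

import fourcpoly as fp
from fourcpoly import bias
from fourcpoly.scaling import FitError, fit_loglog

from conftest import model_pair_matrix, spline_route_pair_matrix


class TestBCP:
    def test_length_normalization(self, uniform_frags):
        vp = fp.Viewpoint("vp", "chrT", 0, 2000)
        counts = np.zeros(uniform_frags.n_fragments, dtype=int)
        counts[10] = 10
        # fragment length is 5000 in the fixture map
        prof = bias.compute_bcp(counts, vp, uniform_frags)
        assert prof.bcp[10] == pytest.approx(10 / (2000 * 5000))
        assert prof.bcp[20] == 0.0

    def test_unit_lengths_identity(self):
        frags = fp.FragmentMap.uniform("c", 10, 1)
        vp = fp.Viewpoint("vp", "c", 0, 1)
        counts = np.arange(10)
        prof = bias.compute_bcp(counts, vp, frags)
        assert np.allclose(prof.bcp, counts)

    def test_self_fragments_flagged(self, uniform_frags):
        vp = fp.Viewpoint("vp", "chrT", 5000, 10000)
        prof = bias.compute_bcp(np.ones(50, dtype=int), vp, uniform_frags)
        assert prof.self_mask[1] and not prof.self_mask[2]
        s, f = prof.fit_values()
        assert s.size == 49


class TestLogLogFit:
    def test_noiseless_power_law_interpolated(self):
        s = np.logspace(4, 7, 100)
        f = s ** -1.5
        fit = fit_loglog(s, f)
        inner = np.logspace(4.2, 6.8, 40)
        assert np.allclose(fit.predict_log(inner), -1.5 * np.log(inner),
                           atol=1e-3)
        assert fit.slope(1e5) == pytest.approx(-1.5, abs=1e-3)

    def test_noisy_power_law_slope(self):
        rng = np.random.default_rng(3)
        s = np.logspace(4, 7, 300)
        f = s ** -1.5 * np.exp(rng.normal(0, 0.2, s.size))
        fit = fit_loglog(s, f)
        assert fit.slope(1e5) == pytest.approx(-1.5, abs=0.1)

    def test_constant_values_zero_slope(self):
        s = np.logspace(4, 7, 60)
        fit = fit_loglog(s, np.full(s.size, 3.7))
        assert np.max(np.abs(fit.slope(np.logspace(4.2, 6.8, 20)))) < 1e-6

    def test_too_few_points_names_viewpoint(self, uniform_frags):
        vp = fp.Viewpoint("vpX", "chrT", 0, 5000)
        counts = np.zeros(50, dtype=int)
        counts[5] = 3
        prof = bias.compute_bcp(counts, vp, uniform_frags)
        with pytest.raises(FitError, match="vpX"):
            bias.fit_loglog_decay(prof)


class TestInterviewpointBCP:
    def _fits(self, scales, positions):
        fits = {}
        for vid, scale in scales.items():
            s = np.logspace(4, 7.5, 80)
            fits[vid] = fit_loglog(s, scale * s ** -1.5,
                                   fit_range=(1e4, 3e7))
        return fits

    def test_identical_fits_symmetric(self):
        vps = [fp.Viewpoint(f"v{i}", "c", int(p), int(p) + 4000)
               for i, p in enumerate(np.linspace(1e6, 9e6, 5))]
        fits = self._fits({v.id: 1.0 for v in vps}, None)
        pm = bias.interviewpoint_bcp(fits, vps)
        assert np.allclose(pm.F, pm.F.T, equal_nan=True, rtol=1e-12)

    def test_factor_two_fits_ratio(self):
        vps = [fp.Viewpoint(f"v{i}", "c", int(p), int(p) + 4000)
               for i, p in enumerate(np.linspace(1e6, 9e6, 4))]
        scales = {"v0": 2.0, "v1": 1.0, "v2": 1.0, "v3": 1.0}
        pm = bias.interviewpoint_bcp(self._fits(scales, None), vps)
        for j in range(1, 4):
            assert pm.F[0, j] / pm.F[j, 0] == pytest.approx(2.0, rel=1e-6)

    def test_off_diagonal_count_is_n_times_n_minus_1(self):
        n = 6
        vps = [fp.Viewpoint(f"v{i}", "c", int(p), int(p) + 4000)
               for i, p in enumerate(np.linspace(1e6, 9e6, n))]
        pm = bias.interviewpoint_bcp(self._fits({v.id: 1.0 for v in vps},
                                                None), vps)
        assert np.sum(np.isfinite(pm.F)) == n * (n - 1)


class TestBiasSolver:
    def test_unbiased_input_is_fixed_point(self):
        pm = model_pair_matrix(np.ones(5), np.ones(5),
                               np.linspace(1e6, 9e6, 5))
        factors, corr = bias.solve_bias_factors(pm)
        assert np.allclose(factors.C, 1.0, atol=1e-10)
        assert np.allclose(factors.K, 1.0, atol=1e-10)
        assert np.allclose(corr.P, corr.P.T, equal_nan=True)

    def test_known_truth_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        n = 6
        C = np.exp(rng.uniform(np.log(0.5), np.log(2), n))
        K = np.exp(rng.uniform(np.log(0.5), np.log(2), n))
        pos = np.sort(rng.uniform(0, 2e7, n))
        pm = model_pair_matrix(C, K, pos)
        factors, corr = bias.solve_bias_factors(pm)
        tC = np.log(C) - np.log(C).mean()
        tK = np.log(K) - np.log(K).mean()
        assert np.allclose(np.log(factors.C), tC, atol=1e-10)
        assert np.allclose(np.log(factors.K), tK, atol=1e-10)
        # the recovered factors reproduce the observations exactly
        Fhat = factors.C[:, None] * factors.C[None, :] \
            * factors.K[:, None] * corr.P
        assert np.allclose(Fhat, pm.F, equal_nan=True, rtol=1e-10)

    def test_three_viewpoints_refused(self):
        pm = model_pair_matrix(np.ones(3), np.ones(3), [1e6, 2e6, 4e6])
        with pytest.raises(bias.IdentifiabilityError):
            bias.solve_bias_factors(pm)

    def test_min_viewpoints_enumeration(self):
        assert bias.min_viewpoints_required() == 4

    def test_gauge_invariance_to_global_rescaling(self):
        rng = np.random.default_rng(5)
        n = 6
        C = np.exp(rng.normal(0, 0.4, n))
        K = np.exp(rng.normal(0, 0.4, n))
        pos = np.sort(rng.uniform(0, 2e7, n))
        f1, _ = bias.solve_bias_factors(model_pair_matrix(C, K, pos))
        f2, _ = bias.solve_bias_factors(model_pair_matrix(3.0 * C, K, pos))
        f3, _ = bias.solve_bias_factors(
            model_pair_matrix(C, K, pos, scale=10.0))
        assert np.allclose(f1.C, f2.C, rtol=1e-9)
        assert np.allclose(f1.K, f2.K, rtol=1e-9)
        assert np.allclose(f1.C, f3.C, rtol=1e-9)

    def test_non_positive_pair_entry_named(self):
        pm = model_pair_matrix(np.ones(4), np.ones(4),
                               np.linspace(1e6, 7e6, 4))
        pm.F[0, 1] = 0.0
        with pytest.raises(ValueError, match="v0.*v1|v1.*v0"):
            bias.solve_bias_factors(pm)

    def test_all_pair_selection_also_works(self):
        rng = np.random.default_rng(2)
        n = 5
        C = np.exp(rng.normal(0, 0.3, n))
        K = np.exp(rng.normal(0, 0.3, n))
        pm = model_pair_matrix(C, K, np.sort(rng.uniform(0, 2e7, n)))
        factors, _ = bias.solve_bias_factors(pm, pair_selection="all")
        assert np.allclose(np.log(factors.K),
                           np.log(K) - np.log(K).mean(), atol=1e-10)


class TestRelativeAsymmetry:
    def test_symmetric_matrix_zero(self):
        M = np.array([[np.nan, 2.0], [2.0, np.nan]])
        out = bias.relative_asymmetry(M)
        assert out[0, 1] == 0.0

    def test_direct_arithmetic(self):
        M = np.array([[np.nan, 2.0], [8.0, np.nan]])
        assert bias.relative_asymmetry(M)[0, 1] == pytest.approx(0.6)

    def test_maximal_asymmetry(self):
        M = np.array([[np.nan, 5.0], [0.0, np.nan]])
        assert bias.relative_asymmetry(M)[0, 1] == pytest.approx(1.0)

    def test_both_zero_undefined(self):
        M = np.zeros((2, 2))
        assert np.isnan(bias.relative_asymmetry(M)[0, 1])


class TestSymmetryRestoration:
    def test_correction_reduces_median_asymmetry(self, biased_experiment):
        """On biased synthetic data the corrected matrix is closer to
        symmetric than the observed one."""
        pm = spline_route_pair_matrix(biased_experiment)
        factors, corr = bias.solve_bias_factors(pm)
        before = bias.median_relative_asymmetry(pm.F)
        after = bias.median_relative_asymmetry(corr.P_directional)
        assert after < before

    def test_experiment_factor_recovered_through_splines(
            self, biased_experiment):
        pm = spline_route_pair_matrix(biased_experiment)
        factors, _ = bias.solve_bias_factors(pm)
        tK = np.log(biased_experiment["K"])
        tK -= tK.mean()
        r = np.corrcoef(np.log(factors.K), tK)[0, 1]
        assert r > 0.75

    def test_correction_product_recovered_through_splines(
            self, biased_experiment):
        """The combination that corrects each profile, C_I*K_I, is pinned
        essentially exactly by the spline route even when the C/K split is
        partially confounded."""
        pm = spline_route_pair_matrix(biased_experiment)
        factors, _ = bias.solve_bias_factors(pm)
        truth = np.log(biased_experiment["C"] * biased_experiment["K"])
        truth -= truth.mean()
        est = np.log(factors.C * factors.K)
        est -= est.mean()
        assert np.corrcoef(est, truth)[0, 1] > 0.99
        assert np.max(np.abs(est - truth)) < 0.1
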