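"""Profile-likelihood machinery checked against closed forms.

A quadratic objective J(ξ) = ½ Σ ξ²/s² has an exactly Gaussian likelihood:
its profile along any axis is R(ξᵢ) = exp(−ξᵢ²/(2sᵢ²)), the likelihood-ratio
interval has half-width sᵢ·√δ_α, and the Hessian-based interval coincides
with the profile interval.  These tests drive the full walker, interval
location, verdict logic and Hessian engine through that closed form.
"""

import numpy as np
import pytest
from scipy.stats import chi2

import rdprofile as rd


def quad_objective(scales):
    scales = np.asarray(scales, dtype=float)

    def objective(xi):
        return 0.5 * float(np.sum((np.asarray(xi) / scales) ** 2))

    return objective


WIDE_BOUNDS = np.tile([-50.0, 50.0], (3, 1))


class TestThreshold:
    def test_chi_square_threshold_98_percent(self):
        """δ_0.98 = χ²(0.98, 1) ≈ 5.412; ratio threshold ≈ 0.0668."""
        assert rd.delta_alpha(0.98) == pytest.approx(5.4119, abs=2e-4)
        assert rd.ratio_threshold(0.98) == pytest.approx(0.06681, abs=2e-5)
        assert rd.delta_alpha(0.95) == pytest.approx(chi2.ppf(0.95, 1), rel=1e-12)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            rd.delta_alpha(1.5)


class TestGaussianToy:
    @pytest.mark.parametrize("index,scale", [(0, 1.0), (1, 0.5), (2, 3.0)])
    def test_profile_matches_closed_form_everywhere(self, index, scale):
        scales = np.array([1.0, 0.5, 3.0])
        prof = rd.profile_objective(quad_objective(scales), np.zeros(3), 0.0,
                                    WIDE_BOUNDS, index)
        expected = np.exp(-0.5 * (prof.grid / scales[index]) ** 2)
        np.testing.assert_allclose(prof.ratio, expected, atol=1e-6)
        assert prof.ratio[np.argmin(np.abs(prof.grid))] == pytest.approx(1.0)

    def test_interval_half_width_is_sqrt_delta(self):
        """CI half-width = s·√δ_α for a Gaussian profile."""
        prof = rd.profile_objective(quad_objective([1.0, 1.0, 1.0]),
                                    np.zeros(3), 0.0, WIDE_BOUNDS, 0)
        hw = np.sqrt(rd.delta_alpha(prof.alpha))
        assert prof.ci.upper_log10 == pytest.approx(hw, abs=5e-3)
        assert prof.ci.lower_log10 == pytest.approx(-hw, abs=5e-3)
        assert prof.verdict == rd.IDENTIFIABLE
        assert not prof.ci.lower_open and not prof.ci.upper_open

    def test_hessian_interval_equals_profile_interval(self):
        scales = np.array([1.0, 0.5, 3.0])
        la = rd.hessian_approximation(quad_objective(scales), np.zeros(3),
                                      alpha=0.98)
        hw_expected = scales * np.sqrt(rd.delta_alpha(0.98))
        np.testing.assert_allclose(la.half_widths_log10, hw_expected, rtol=1e-5)
        assert la.reliable

    def test_hessian_permutation_invariance(self):
        scales = np.array([1.0, 0.5, 3.0])
        la = rd.hessian_approximation(quad_objective(scales), np.zeros(3))
        la_rev = rd.hessian_approximation(quad_objective(scales[::-1]),
                                          np.zeros(3))
        np.testing.assert_allclose(la.hessian, la_rev.hessian[::-1, ::-1].T,
                                   atol=1e-8)

    def test_correlated_quadratic_profile_uses_reoptimization(self):
        """With strong parameter correlation the profile must be wider than
        the fixed-at-optimum slice: variance inflation 1/(1−ρ²)."""
        rho = 0.9
        prec = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))

        def objective(xi):
            x = np.asarray(xi)
            return 0.5 * float(x @ prec @ x)

        prof = rd.profile_objective(objective, np.zeros(2), 0.0,
                                    np.tile([-50.0, 50.0], (2, 1)), 0)
        expected = np.exp(-0.5 * prof.grid**2)  # marginal variance is 1
        np.testing.assert_allclose(prof.ratio, expected, atol=1e-6)

    def test_bound_limited_profile_flagged_open(self):
        """A flat direction that never crosses the threshold inside the box
        is practically non-identifiable with the open side recorded."""
        scales = np.array([100.0, 1.0])  # axis 0 essentially flat in the box
        bounds = np.tile([-2.0, 1.0], (2, 1))
        prof = rd.profile_objective(quad_objective(scales), np.zeros(2), 0.0,
                                    bounds, 0)
        assert prof.verdict == rd.NON_IDENTIFIABLE
        assert prof.ci.lower_open and prof.ci.upper_open
        assert prof.ci.lower_log10 == pytest.approx(-2.0)
        assert prof.ci.upper_log10 == pytest.approx(1.0)
        assert prof.lower_bound_hit and prof.upper_bound_hit

    def test_one_sided_openness(self):
        """An optimum near the lower box edge of a gentle direction leaves
        only the lower side open."""
        bounds = np.array([[-2.0, 50.0]])
        prof = rd.profile_objective(quad_objective([1.5]), np.array([-1.0]),
                                    0.0, bounds, 0,
                                    options=rd.ProfileOptions(alpha=0.98))
        # lower crossing would sit at -1 - 1.5·√δ ≈ -4.5 < box edge -2
        assert prof.ci.lower_open and not prof.ci.upper_open
        assert prof.verdict == rd.NON_IDENTIFIABLE

    def test_flat_profile_both_ends_open(self):
        prof = rd.profile_objective(lambda xi: 0.0, np.zeros(2), 0.0,
                                    np.tile([-2.0, 1.0], (2, 1)), 0)
        assert prof.verdict == rd.NON_IDENTIFIABLE
        assert prof.ci.lower_open and prof.ci.upper_open
        np.testing.assert_allclose(prof.ratio, 1.0)

    def test_profile_dominates_optimum(self):
        prof = rd.profile_objective(quad_objective([1.0, 2.0]), np.zeros(2),
                                    0.0, np.tile([-50.0, 50.0], (2, 1)), 1)
        assert np.all(prof.nll_profile >= prof.nll_ref - 1e-12)

    def test_warm_start_independence_on_toy(self):
        """Profile J values agree whether inner optimizations warm-start
        from the previous point (engine default) or could start anywhere:
        for the convex toy the engine must find the exact inner optimum."""
        rho = 0.8
        prec = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))

        def objective(xi):
            x = np.asarray(xi)
            return 0.5 * float(x @ prec @ x)

        prof = rd.profile_objective(objective, np.zeros(2), 0.0,
                                    np.tile([-50.0, 50.0], (2, 1)), 0)
        # exact inner optimum: J_prof(x0) = x0²/2 (marginal variance 1)
        np.testing.assert_allclose(prof.nll_profile, 0.5 * prof.grid**2,
                                   atol=1e-4)


class TestConfidenceIntervalEdges:
    def test_recompute_at_different_alpha_nested(self):
        prof = rd.profile_objective(quad_objective([1.0, 1.0]), np.zeros(2),
                                    0.0, np.tile([-50.0, 50.0], (2, 1)), 0)
        ci90 = rd.confidence_interval(prof, alpha=0.90)
        ci98 = rd.confidence_interval(prof, alpha=0.98)
        assert ci90.upper_log10 < ci98.upper_log10
        assert ci90.lower_log10 > ci98.lower_log10

    def test_too_few_points_rejected(self):
        prof = rd.profile_objective(quad_objective([1.0]), np.zeros(1), 0.0,
                                    np.array([[-50.0, 50.0]]), 0)
        bad = rd.ProfileResult(
            parameter="x", index=0, grid=np.array([0.0]),
            nll_profile=np.array([0.0]), ratio=np.array([1.0]),
            nll_ref=0.0, nll_opt=0.0, xi_hat=0.0, alpha=0.98,
            delta=prof.delta, bounds_log10=(-50.0, 50.0),
            lower_bound_hit=False, upper_bound_hit=False)
        with pytest.raises(ValueError):
            rd.confidence_interval(bad)
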