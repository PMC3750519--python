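"""Log-normal likelihood: closed forms, naive-summation oracle, analytic
noise-variance profile."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rdprofile as rd


def naive_nll(y_obs, y_pred, sigma2):
    """Independent brute-force oracle: per-observation log-density summed
    with plain Python floats."""
    total = 0.0
    sigma = math.sqrt(sigma2)
    for yo, yp in zip(np.ravel(y_obs), np.ravel(y_pred)):
        total += math.log(math.sqrt(2 * math.pi) * sigma * yo)
        total += (math.log(yo) - math.log(yp)) ** 2 / (2 * sigma2)
    return total


class TestLogNormalNLL:
    def test_single_observation_closed_form(self):
        """ȳ = 1, y = e, σ = 1 ⇒ J = log√(2π) + 1/2."""
        val = rd.lognormal_nll([1.0], [math.e], 1.0)
        assert val == pytest.approx(math.log(math.sqrt(2 * math.pi)) + 0.5, rel=1e-14)

    def test_perfect_fit_leaves_normalization_terms(self):
        y = np.array([0.3, 1.7, 2.2])
        expected = sum(math.log(math.sqrt(2 * math.pi) * v) for v in y)
        assert rd.lognormal_nll(y, y, 1.0) == pytest.approx(expected, rel=1e-14)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        sigma2=st.floats(1e-6, 10.0),
        n=st.integers(1, 40),
    )
    def test_matches_naive_summation_oracle(self, seed, sigma2, n):
        rng = np.random.default_rng(seed)
        y_obs = rng.lognormal(0, 1, n)
        y_pred = rng.lognormal(0, 1, n)
        fast = rd.lognormal_nll(y_obs, y_pred, sigma2)
        assert fast == pytest.approx(naive_nll(y_obs, y_pred, sigma2), rel=1e-12)

    def test_rejects_non_positive_inputs(self):
        with pytest.raises(ValueError):
            rd.lognormal_nll([0.0], [1.0], 1.0)
        with pytest.raises(ValueError):
            rd.lognormal_nll([1.0], [-1.0], 1.0)
        with pytest.raises(ValueError):
            rd.lognormal_nll([1.0], [1.0], 0.0)


class TestProfileSigma2:
    def test_zero_residuals_hit_floor(self):
        assert rd.profile_sigma2(np.zeros(10)) == pytest.approx(1e-12)

    def test_hand_computed_value(self):
        assert rd.profile_sigma2([1.0, -1.0]) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rd.profile_sigma2([])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 500), n=st.integers(2, 30))
    def test_analytic_profile_beats_any_numeric_sigma2(self, seed, n):
        """σ̂² = mean(r²) minimizes the NLL over σ² at fixed residuals."""
        rng = np.random.default_rng(seed)
        r = rng.normal(0, 0.3, n)
        y_obs = np.exp(rng.normal(0, 0.5, n))
        y_pred = y_obs / np.exp(r)  # log y_obs - log y_pred = r
        s2_hat = rd.profile_sigma2(r)
        best = rd.lognormal_nll(y_obs, y_pred, s2_hat)
        for s2 in np.geomspace(s2_hat / 100, s2_hat * 100, 31):
            assert best <= rd.lognormal_nll(y_obs, y_pred, s2) + 1e-9

    def test_variance_mle_consistent_on_benchmark_data(self, dataset, ctx):
        """σ̂² at the true kinetics averages to the generating σ² = 10⁻⁴
        across noise realizations."""
        vals = []
        for seed in range(10):
            noisy = rd.add_noise(dataset.clean, rd.NoiseSpec(sigma2=1e-4, seed=seed))
            ov = rd.neg_log_likelihood(dataset.truth, noisy, ctx, profile_noise=True)
            vals.append(ov.sigma2_hat)
        n_obs = dataset.clean.values.size
        se = 1e-4 * np.sqrt(2.0 / n_obs) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1e-4) < 4 * se


class TestNegLogLikelihood:
    def test_matches_naive_oracle_through_the_model(self, dataset, ctx):
        ov = rd.neg_log_likelihood(dataset.truth, dataset.noisy, ctx)
        pred = rd.predict(dataset.truth, dataset.noisy, ctx)
        expected = naive_nll(dataset.noisy.values, pred.values, dataset.truth.sigma2)
        assert ov.nll == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(
            ov.residuals, np.log(dataset.noisy.values) - np.log(pred.values))

    def test_profiled_noise_never_worse(self, dataset, ctx):
        fixed = rd.neg_log_likelihood(dataset.truth, dataset.noisy, ctx,
                                      profile_noise=False)
        profiled = rd.neg_log_likelihood(dataset.truth, dataset.noisy, ctx,
                                         profile_noise=True)
        assert profiled.nll <= fixed.nll + 1e-9

    def test_truth_beats_perturbed_kinetics_on_average(self, dataset, ctx):
        """Expected J is minimized near the generating parameters: across
        seeds, doubling any kinetic parameter (except the weakly informed
        degradation rate) increases J in most realizations."""
        wins = {name: 0 for name in ("D", "alpha", "k1", "km1")}
        n_seeds = 5
        for seed in range(n_seeds):
            noisy = rd.add_noise(dataset.clean, rd.NoiseSpec(sigma2=1e-4, seed=seed))
            j_true = rd.neg_log_likelihood(dataset.truth, noisy, ctx).nll
            for name in wins:
                pert = dataset.truth.replace(
                    **{name: getattr(dataset.truth, name) * 2.0})
                if rd.neg_log_likelihood(pert, noisy, ctx).nll > j_true:
                    wins[name] += 1
        assert all(w == n_seeds for w in wins.values()), wins

    def test_solver_failure_becomes_inf_sentinel(self, dataset, ctx, monkeypatch):
        def boom(*a, **k):
            raise rd.SolverFailure("synthetic failure")

        monkeypatch.setattr("rdprofile.likelihood.simulate", boom)
        ov = rd.neg_log_likelihood(dataset.truth, dataset.noisy, ctx)
        assert ov.nll == np.inf and ov.residuals is None
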