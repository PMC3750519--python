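"""Forward model: RHS structure, conservation, closed-form limits,
grid convergence and failure handling."""

import numpy as np
import pytest

import rdprofile as rd
from rdprofile.model import neumann_laplacian

from conftest import TEST_ATOL, TEST_RTOL


class TestParameters:
    def test_kinetics_order_and_log10_roundtrip(self, truth):
        np.testing.assert_allclose(truth.kinetics, [0.5, 0.1, 5, 1, 0.1])
        back = truth.with_log10_kinetics(truth.log10_kinetics)
        np.testing.assert_allclose(back.kinetics, truth.kinetics)

    def test_default_bounds_are_decade_box(self, truth):
        np.testing.assert_allclose(truth.log10_bounds,
                                   np.tile([-2.0, 1.0], (5, 1)))
        assert truth.in_bounds()

    @pytest.mark.parametrize("bad", [{"D": -1.0}, {"k1": 0.0}, {"sigma2": 0.0},
                                     {"b": -1e-5}])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(D=0.5, alpha=0.1, k1=5.0, km1=1.0, gamma=0.1)
        kw.update(bad)
        with pytest.raises(ValueError):
            rd.ModelParameters(**kw)


class TestRHS:
    def test_trivial_equilibrium(self, grid, source, truth):
        """p = c = 0, s = s0 and no release ⇒ nothing moves."""
        params = truth.replace(alpha=1e-300)  # effectively zero release
        n = grid.n_nodes
        state = np.concatenate([np.zeros(n), np.ones(n), np.zeros(n)])
        deriv = rd.rhs(state, 0.0, params, source, grid)
        np.testing.assert_allclose(deriv, 0.0, atol=1e-290)

    def test_substrate_complex_conservation_by_construction(self, grid, source, truth):
        rng = np.random.default_rng(0)
        state = rng.uniform(0.1, 1.0, 3 * grid.n_nodes)
        deriv = rd.rhs(state, 0.0, truth, source, grid)
        n = grid.n_nodes
        np.testing.assert_allclose(deriv[n:2 * n] + deriv[2 * n:], 0.0, atol=1e-14)

    def test_neumann_laplacian_annihilates_constants(self, grid):
        lap = neumann_laplacian(grid.nx, grid.dx)
        np.testing.assert_allclose(lap @ np.ones(grid.n_nodes), 0.0, atol=1e-9)

    def test_non_finite_state_raises(self, grid, source, truth):
        state = np.full(3 * grid.n_nodes, np.nan)
        with pytest.raises(rd.SolverFailure):
            rd.rhs(state, 0.0, truth, source, grid)


class TestSimulate:
    def test_no_source_limit_of_alpha(self, grid, source, truth):
        """α → 0 freezes the system at the initial condition."""
        params = truth.replace(alpha=1e-300)
        traj = rd.simulate(params, source, grid, [0.5, 1.0],
                           rtol=TEST_RTOL, atol=TEST_ATOL)
        assert np.abs(traj.p).max() < 1e-12
        assert np.abs(traj.c).max() < 1e-12
        np.testing.assert_allclose(traj.s, 1.0, atol=1e-12)

    def test_conservation_and_positivity_at_truth(self, traj):
        assert traj.conservation_error() <= 1e-6
        assert traj.min_value() >= -1e-8

    def test_heat_equation_cosine_mode(self):
        """With no reactions, p(t, x) = exp(−D π² t) cos(π x₁) under Neumann
        boundaries; the solver must match the closed form to O(dx²)."""
        D, t_end = 0.5, 0.1
        errors = {}
        for nx in (16, 32):
            g = rd.DomainGrid(nx=nx)
            X, _ = g.mesh()
            # reaction-free: k1, km1, gamma, alpha at (numerically) zero
            params = rd.ModelParameters(D=D, alpha=1e-300, k1=1e-300,
                                        km1=1e-300, gamma=1e-300)
            src = rd.SourceMap(values=np.ones((nx, nx)), grid=g)
            traj = rd.simulate(params, src, g, [t_end], rtol=1e-10, atol=1e-12,
                               initial_fields=(np.cos(np.pi * X),
                                               np.zeros((nx, nx)),
                                               np.zeros((nx, nx))))
            exact = np.exp(-D * np.pi**2 * t_end) * np.cos(np.pi * X)
            errors[nx] = np.abs(traj.p[0] - exact).max()
        assert errors[32] < 5e-3
        # halving dx should shrink the error ~4x (second order)
        assert 2.5 < errors[16] / errors[32] < 6.0

    def test_grid_convergence_second_order_smooth_source(self, truth):
        """L² error of c(T, ·) between successive refinements shrinks ~4×
        for an analytic smooth source."""
        sols = {}
        for nx in (16, 32, 64):
            g = rd.DomainGrid(nx=nx)
            src = rd.gaussian_bump_source(g, center=(0.5, 0.4), radius=0.15)
            traj = rd.simulate(truth, src, g, [0.5], rtol=1e-9, atol=1e-11)
            sols[nx] = traj.c[0]

        def coarsen(f, factor):
            n = f.shape[0] // factor
            return f.reshape(n, factor, n, factor).mean(axis=(1, 3))

        e1 = np.sqrt(np.sum((coarsen(sols[32], 2) - sols[16]) ** 2) * (1 / 16) ** 2)
        e2 = np.sqrt(np.sum((coarsen(sols[64], 2) - sols[32]) ** 2) * (1 / 32) ** 2)
        assert 2.5 < e1 / e2 < 6.0

    def test_steady_state_residual_decreases(self, grid, source, truth):
        """With γ > 0 the p-field time derivative decays toward steady state."""
        times = [1.0, 4.0, 16.0, 64.0]
        traj = rd.simulate(truth, source, grid, times,
                           rtol=TEST_RTOL, atol=TEST_ATOL)
        res = []
        n = grid.n_nodes
        for k in range(len(times)):
            state = np.concatenate([traj.p[k].ravel(), traj.s[k].ravel(),
                                    traj.c[k].ravel()])
            deriv = rd.rhs(state, times[k], truth, source, grid)
            res.append(np.abs(deriv[:n]).max())
        assert all(a > b for a, b in zip(res, res[1:]))
        assert res[-1] < 0.5 * res[0]

    def test_output_time_validation(self, grid, source, truth):
        for bad in ([], [0.0, 0.5], [0.5, 0.4]):
            with pytest.raises(ValueError):
                rd.simulate(truth, source, grid, bad)

    def test_mismatched_source_grid_rejected(self, truth, source):
        other = rd.DomainGrid(nx=8)
        with pytest.raises(ValueError):
            rd.simulate(truth, source, other, [1.0])
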