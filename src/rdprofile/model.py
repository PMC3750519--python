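"""Haptotaxis gradient-formation model and its forward solver.

Three fields live on the unit square: freely diffusing signaling protein
``p`` (e.g. the chemokine CCL21 released by lymphatic vessels), immobile
binding substrate ``s`` (tissue-bound sugars of the extracellular matrix),
and the immobilized complex ``c`` that microscopy stainings visualize:

    ∂ₜp = D Δp + α Q − k₁ p s + k₋₁ c − γ p
    ∂ₜs =             − k₁ p s + k₋₁ c
    ∂ₜc =               k₁ p s − k₋₁ c

with no-flux boundary conditions for ``p``, initial conditions
``p = c = 0``, ``s = s₀ ≡ 1``, and a binary release region Q.  Only ``p``
diffuses.  The sum ``s + c`` is conserved pointwise, which the tests use as
an integration diagnostic.

Spatial discretization is a 5-point Laplacian on a cell-centered grid with
ghost-node reflection for the Neumann boundary; time integration is a
stiff-capable implicit method of lines (BDF) with an analytic sparse
Jacobian.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .errors import SolverFailure
from .grid import DomainGrid
from .sources import SourceMap

#: order of the kinetic parameters throughout the package
KINETIC_NAMES = ("D", "alpha", "k1", "km1", "gamma")

#: default box constraints for each kinetic parameter
DEFAULT_KINETIC_BOUNDS = (1e-2, 1e1)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic parameters θ = (D, α, k₁, k₋₁, γ) plus observation parameters.

    Parameters
    ----------
    D : float
        Diffusion coefficient of the free protein (space²/time).
    alpha : float
        Release rate from the source region (concentration/time).
    k1 : float
        Binding rate of protein to substrate (1/(concentration·time)).
    km1 : float
        Unbinding rate of the complex (1/time).
    gamma : float
        Degradation rate of the free protein (1/time).
    b : float
        Constant background intensity offset (≥ 0); strictly positive values
        keep the multiplicative noise model well defined on dark pixels.
    sigma2 : float
        Variance of the log-intensity noise (dimensionless, log scale).
    bounds : tuple of (lower, upper) pairs, optional
        Box constraints for the five kinetic parameters, in the order of
        :data:`KINETIC_NAMES`.  Defaults to [10⁻², 10¹] for every parameter.
    """

    D: float
    alpha: float
    k1: float
    km1: float
    gamma: float
    b: float = 1e-4
    sigma2: float = 1e-4
    bounds: tuple = field(default=tuple(DEFAULT_KINETIC_BOUNDS for _ in KINETIC_NAMES))

    def __post_init__(self):
        for name in KINETIC_NAMES:
            v = getattr(self, name)
            if not (v > 0) or not np.isfinite(v):
                raise ValueError(f"kinetic parameter {name} must be strictly positive, got {v!r}")
        if not (self.sigma2 > 0):
            raise ValueError(f"sigma2 must be strictly positive, got {self.sigma2!r}")
        if self.b < 0:
            raise ValueError(f"b must be non-negative, got {self.b!r}")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if len(bounds) != len(KINETIC_NAMES) or any(not (0 < lo < hi) for lo, hi in bounds):
            raise ValueError(f"bounds must be 5 pairs 0 < lower < upper, got {self.bounds!r}")
        object.__setattr__(self, "bounds", bounds)

    @property
    def kinetics(self) -> np.ndarray:
        """The five kinetic parameters as an array in :data:`KINETIC_NAMES` order."""
        return np.array([self.D, self.alpha, self.k1, self.km1, self.gamma])

    @property
    def log10_kinetics(self) -> np.ndarray:
        return np.log10(self.kinetics)

    @property
    def log10_bounds(self) -> np.ndarray:
        """Box constraints in log10 space, shape (5, 2)."""
        return np.log10(np.asarray(self.bounds, dtype=float))

    def with_kinetics(self, values) -> "ModelParameters":
        """Return a copy with the kinetic parameters replaced (linear scale)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise ValueError(f"expected 5 kinetic values, got shape {values.shape}")
        return dataclasses.replace(self, **dict(zip(KINETIC_NAMES, values)))

    def with_log10_kinetics(self, xi) -> "ModelParameters":
        """Return a copy with kinetics set to ``10**xi``."""
        return self.with_kinetics(np.power(10.0, np.asarray(xi, dtype=float)))

    def in_bounds(self, rtol: float = 1e-12) -> bool:
        theta = self.kinetics
        lo, hi = np.asarray(self.bounds).T
        return bool(np.all(theta >= lo * (1 - rtol)) and np.all(theta <= hi * (1 + rtol)))

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


def default_true_parameters() -> ModelParameters:
    """Ground-truth parameter set of the built-in benchmark scenario:
    θ = (D, α, k₁, k₋₁, γ) = (0.5, 0.1, 5, 1, 0.1), b = 10⁻⁴, σ² = (10⁻²)²."""
    return ModelParameters(D=0.5, alpha=0.1, k1=5.0, km1=1.0, gamma=0.1, b=1e-4, sigma2=1e-4)


@dataclass(frozen=True)
class StateTrajectory:
    """Solution fields on the grid at the requested output times.

    ``p``, ``s`` and ``c`` have shape ``(n_times, nx, nx)``.
    """

    times: np.ndarray
    p: np.ndarray
    s: np.ndarray
    c: np.ndarray
    grid: DomainGrid
    s0: float = 1.0

    def conservation_error(self) -> float:
        """max over times and nodes of |s + c − s₀| (zero in the continuum)."""
        return float(np.abs(self.s + self.c - self.s0).max())

    def min_value(self) -> float:
        """Most negative field value anywhere (≈0 up to solver tolerance)."""
        return float(min(self.p.min(), self.s.min(), self.c.min()))


@lru_cache(maxsize=16)
def neumann_laplacian(nx: int, dx: float) -> sp.csr_matrix:
    """5-point Laplacian on an nx×nx cell-centered grid with zero-flux
    (ghost-node reflection) boundaries, as a CSR matrix of size nx²×nx².

    Constants are in its null space (row sums are zero), so a spatially
    uniform field does not diffuse.
    """
    main = np.full(nx, -2.0)
    main[0] = main[-1] = -1.0  # ghost reflection: boundary cell sees itself
    off = np.ones(nx - 1)
    t = sp.diags([off, main, off], [-1, 0, 1], format="csr") / dx**2
    eye = sp.identity(nx, format="csr")
    return (sp.kron(eye, t) + sp.kron(t, eye)).tocsr()


def rhs(state, t, params: ModelParameters, source: SourceMap, grid: DomainGrid,
        laplacian: sp.spmatrix | None = None) -> np.ndarray:
    """Time derivative of the flattened state ``[p, s, c]`` (3·nx² entries).

    Exposed mainly for testing and for reuse with other integrators; the
    forward solver builds a cached closure around the same arithmetic.
    """
    state = np.asarray(state, dtype=float)
    n = grid.n_nodes
    if state.shape != (3 * n,):
        raise ValueError(f"state must have {3 * n} entries, got shape {state.shape}")
    if not np.all(np.isfinite(state)):
        raise SolverFailure("non-finite state passed to rhs", params=params)
    if laplacian is None:
        laplacian = neumann_laplacian(grid.nx, grid.dx)
    p, s, c = state[:n], state[n:2 * n], state[2 * n:]
    bind = params.k1 * p * s - params.km1 * c
    dp = params.D * (laplacian @ p) + params.alpha * source.values.ravel() - bind - params.gamma * p
    return np.concatenate([dp, -bind, bind])


def _reduced_system(params: ModelParameters, laplacian, q, total, n):
    """RHS and Jacobian of the (p, c) system after exact elimination of the
    substrate via the pointwise invariant s(t, x) = total(x) − c(t, x)."""
    k1, km1, gamma, D = params.k1, params.km1, params.gamma, params.D

    def f(t, u):
        p, c = u[:n], u[n:]
        bind = k1 * p * (total - c) - km1 * c
        dp = D * (laplacian @ p) + q - bind - gamma * p
        return np.concatenate([dp, bind])

    def jac(t, u):
        p, c = u[:n], u[n:]
        s = total - c
        d_bind_dp = sp.diags(k1 * s)
        d_bind_dc = sp.diags(-k1 * p - km1)
        return sp.bmat(
            [
                [D * laplacian - d_bind_dp - sp.diags(np.full(n, gamma)), -d_bind_dc],
                [d_bind_dp, d_bind_dc],
            ],
            format="csc",
        )

    return f, jac


def simulate(
    params: ModelParameters,
    source: SourceMap,
    grid: DomainGrid,
    output_times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "BDF",
    s0: float = 1.0,
    initial_fields=None,
) -> StateTrajectory:
    """Integrate the model forward and return the fields at ``output_times``.

    Parameters
    ----------
    output_times : array-like
        Strictly increasing, all > 0.
    rtol, atol : float
        Integrator tolerances (method of lines, implicit BDF by default with
        an analytic sparse Jacobian).
    initial_fields : (p0, s0_field, c0) triple of (nx, nx) arrays, optional
        Testing hook overriding the standard initial condition
        ``p = c = 0, s = s₀``; not part of the fitting API.

    Raises
    ------
    SolverFailure
        If the integrator does not reach the final time within tolerance;
        the exception carries ``params`` so optimizers can penalize the
        point and continue.
    """
    times = np.asarray(output_times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("output_times must be a non-empty 1D sequence")
    if times[0] <= 0 or np.any(np.diff(times) <= 0):
        raise ValueError("output_times must be strictly increasing and > 0")
    if source.grid != grid:
        raise ValueError("source was built on a different grid")

    n = grid.n_nodes
    # The substrate is eliminated exactly via the pointwise conservation law
    # ∂ₜ(s + c) = 0: only (p, c) are integrated, and s(t,x) = total(x) − c(t,x)
    # with total(x) = s(0,x) + c(0,x).
    if initial_fields is None:
        u0 = np.concatenate([np.zeros(n), np.zeros(n)])
        total = np.full(n, float(s0))
    else:
        p0, s0f, c0 = (np.asarray(f, dtype=float) for f in initial_fields)
        for name, f in (("p0", p0), ("s0", s0f), ("c0", c0)):
            if f.shape != (grid.nx, grid.nx):
                raise ValueError(f"initial field {name} has shape {f.shape}, "
                                 f"expected ({grid.nx}, {grid.nx})")
        u0 = np.concatenate([p0.ravel(), c0.ravel()])
        total = (s0f + c0).ravel()

    lap = neumann_laplacian(grid.nx, grid.dx)
    q = params.alpha * source.values.ravel()
    f, jac = _reduced_system(params, lap, q, total, n)
    sol = solve_ivp(
        f,
        (0.0, float(times[-1])),
        u0,
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac=jac if method in ("BDF", "Radau") else None,
    )
    if sol.status != 0 or not np.all(np.isfinite(sol.y)):
        raise SolverFailure(
            f"time integration failed at θ={params.kinetics}: {sol.message}", params=params
        )
    shape = (times.size, grid.nx, grid.nx)
    c = sol.y[n:].T.reshape(shape)
    return StateTrajectory(
        times=times,
        p=sol.y[:n].T.reshape(shape),
        s=total.reshape(1, grid.nx, grid.nx) - c,
        c=c,
        grid=grid,
        s0=float(s0),
    )
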