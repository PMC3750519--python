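"""Profile likelihoods, confidence intervals and practical identifiability.

For parameter θᵢ the profile likelihood is the likelihood re-maximized over
all other parameters with θᵢ held fixed,

    PL(θᵢ) = max_{θ_j, j≠i} L(θ) = exp(−min_{θ_j, j≠i} J(θ)),

and the likelihood ratio R(θᵢ) = PL(θᵢ)/L(θ*).  The pointwise confidence
set at level α collects the θᵢ with −2 log R(θᵢ) ≤ δ_α where
δ_α = χ²(α, 1); a parameter is practically non-identifiable when the ratio
fails to drop below exp(−δ_α/2) on at least one side within the admissible
box.  A Hessian-based quadratic expansion of J at the optimum provides the
classical asymptotic intervals for comparison; profiles expose where that
local picture breaks down.

Profiles are computed on the log10 parameter scale (the same scale used for
optimization), with adaptive stepping and warm-started inner optimizations.
The engine works on any objective ``J(ξ)``, which the test-suite uses to
check it against closed-form quadratic likelihoods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .estimation import FitResult, objective_in_log_space
from .likelihood import ModelContext
from .model import KINETIC_NAMES
from .observation import ImageSeries

logger = logging.getLogger(__name__)

IDENTIFIABLE = "identifiable"
NON_IDENTIFIABLE = "practically non-identifiable"


def delta_alpha(alpha: float) -> float:
    """Likelihood-ratio threshold δ_α = χ²(α, 1) for pointwise intervals."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    return float(chi2.ppf(alpha, 1))


def ratio_threshold(alpha: float) -> float:
    """The likelihood-ratio value exp(−δ_α/2) at the confidence boundary."""
    return float(np.exp(-0.5 * delta_alpha(alpha)))


@dataclass(frozen=True)
class ProfileOptions:
    """Tuning of the profile walker.

    ``init_step`` is the first step in log10 units; the step doubles when a
    step changes J by less than ``flat_dj`` and halves when it changes J by
    more than ``steep_dj``.  The walk stops once R drops below
    ``stop_margin · exp(−δ_α/2)`` or the box bound is reached.  Threshold
    crossings are localized by bisection until the bracketing −2ΔlogL gap
    falls below ``refine_gap``.
    """

    alpha: float = 0.98
    init_step: float = 0.02
    min_step: float = 1e-4
    max_step: float = 0.5
    flat_dj: float = 0.1
    steep_dj: float = 1.0
    stop_margin: float = 0.1
    max_points: int = 100
    refine_gap: float = 1.5
    refine_max: int = 10
    inner_method: str = "L-BFGS-B"
    inner_tol: float = 1e-9
    inner_max_iter: int = 40
    inner_simplex: float = 0.01


@dataclass(frozen=True)
class ConfidenceInterval:
    """Likelihood-ratio confidence interval with open-end flags.

    ``lower``/``upper`` are on the linear parameter scale; an open end means
    the threshold was never crossed before the box bound, and the endpoint
    then reports the bound itself.
    """

    lower: float
    upper: float
    lower_log10: float
    upper_log10: float
    lower_open: bool
    upper_open: bool
    alpha: float
    delta: float

    @property
    def width_log10(self) -> float:
        return self.upper_log10 - self.lower_log10

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ProfileResult:
    """Profile of one parameter: grid (log10), re-optimized J, ratio trace,
    interval and verdict."""

    parameter: str
    index: int
    grid: np.ndarray
    nll_profile: np.ndarray
    ratio: np.ndarray
    nll_ref: float
    nll_opt: float
    xi_hat: float
    alpha: float
    delta: float
    bounds_log10: tuple[float, float]
    lower_bound_hit: bool
    upper_bound_hit: bool
    n_failed: int = 0
    ci: ConfidenceInterval | None = None
    verdict: str | None = None

    def two_delta_log_l(self) -> np.ndarray:
        """−2 log R at every profile point."""
        return 2.0 * (self.nll_profile - self.nll_ref)


@dataclass(frozen=True)
class LocalApproximation:
    """Quadratic (Hessian-based) expansion of J at the optimum.

    The Hessian is taken in log10-parameter coordinates by central second
    differences.  The profile of a quadratic objective along axis i has
    curvature 1/(H⁻¹)ᵢᵢ, giving the asymptotic interval half-width
    √(δ_α · (H⁻¹)ᵢᵢ) in log10 units.
    """

    hessian: np.ndarray
    xi_hat: np.ndarray
    nll_opt: float
    alpha: float
    delta: float
    parameters: tuple[str, ...]
    half_widths_log10: np.ndarray
    ci_log10: np.ndarray
    ci: np.ndarray
    reliable: bool

    def quadratic_ratio(self, index: int, xi_values) -> np.ndarray:
        """Likelihood-ratio trace of the quadratic model along one axis."""
        xi_values = np.asarray(xi_values, dtype=float)
        hw = self.half_widths_log10[index]
        curv = self.delta / hw**2 if np.isfinite(hw) and hw > 0 else np.inf
        return np.exp(-0.5 * curv * (xi_values - self.xi_hat[index]) ** 2)


# ---------------------------------------------------------------------------
# generic 1-D profiling engine


def _reduced_minimize(objective, index, value, x_warm, bounds, options: ProfileOptions,
                      x_alt=None):
    """Minimize the objective over all coordinates except ``index`` (held at
    ``value``), warm-started at ``x_warm``; returns (J, x_full, ok).

    ``x_alt`` is an optional second promising start (e.g. the previous
    profile optimum when ``x_warm`` is an extrapolation); for the simplex
    inner method it becomes a vertex so the search spans the ridge
    direction between the two.
    """
    d = len(x_warm)
    free = [j for j in range(d) if j != index]
    if not free:  # one-dimensional objective: nothing to re-optimize
        x = np.array(x_warm, dtype=float)
        x[index] = value
        return float(objective(x)), x, True

    def fr(xr):
        x = np.array(x_warm, dtype=float)
        x[index] = value
        x[free] = xr
        return objective(x)

    sub_bounds = [tuple(bounds[j]) for j in free]
    lo = np.array([b[0] for b in sub_bounds])
    hi = np.array([b[1] for b in sub_bounds])
    x0 = np.clip([x_warm[j] for j in free], lo, hi)
    opts: dict = {"maxiter": options.inner_max_iter}
    if options.inner_method == "L-BFGS-B":
        opts.update({"ftol": options.inner_tol, "eps": 1e-5, "maxcor": 20})
    elif options.inner_method == "Nelder-Mead":
        # warm starts sit close to the inner optimum: a small initial
        # simplex converges in few, cheap (gradient-free) evaluations
        h = options.inner_simplex
        vertices = [x0]
        if x_alt is not None:
            alt = np.clip([x_alt[j] for j in free], lo, hi)
            if np.linalg.norm(alt - x0) > 1e-9:
                vertices.append(alt)
        ridge = vertices[1] - x0 if len(vertices) > 1 else None
        # complete with the coordinate steps least aligned with the ridge
        order = (np.argsort(np.abs(ridge)) if ridge is not None
                 else np.arange(len(x0)))
        for j in order:
            if len(vertices) == len(x0) + 1:
                break
            step = np.zeros(len(x0))
            step[j] = h if x0[j] + h <= hi[j] else -h
            vertices.append(np.clip(x0 + step, lo, hi))
        opts.update({"fatol": 1e-4, "xatol": 2e-4,
                     "initial_simplex": np.vstack(vertices)})
    res = optimize.minimize(fr, x0, method=options.inner_method,
                            bounds=sub_bounds, options=opts)
    x = np.array(x_warm, dtype=float)
    x[index] = value
    x[free] = res.x
    ok = np.isfinite(res.fun)
    return float(res.fun), x, ok


def _walk_direction(objective, index, xi_hat, nll_opt, bounds, sign, options: ProfileOptions):
    """Walk the profile away from the optimum in one direction.

    Returns (points, bound_hit, n_failed) where points is a list of
    (value, nll) pairs excluding the optimum itself.
    """
    delta = delta_alpha(options.alpha)
    stop_nll = nll_opt + 0.5 * delta - np.log(options.stop_margin)
    bound = bounds[index][0] if sign < 0 else bounds[index][1]
    points: list[tuple[float, float]] = []
    n_failed = 0
    value, nll_here = float(xi_hat[index]), nll_opt
    x_warm = np.array(xi_hat, dtype=float)
    x_prev = None  # previous profile optimum, for warm-start extrapolation
    step = options.init_step
    bound_hit = False
    crossed = False

    for _ in range(options.max_points):
        at_bound = False
        nxt = value + sign * step
        if (sign > 0 and nxt >= bound) or (sign < 0 and nxt <= bound):
            nxt = bound
            at_bound = True
        # predict where the re-optimized parameters move by extrapolating
        # the path of inner optima (they travel along the correlation ridge);
        # the previous optimum stays available as an alternative start
        start, alt = x_warm, None
        if x_prev is not None and x_warm[index] != x_prev[index]:
            frac = (nxt - x_warm[index]) / (x_warm[index] - x_prev[index])
            frac = float(np.clip(frac, 0.0, 1.5))
            start = np.clip(x_warm + frac * (x_warm - x_prev),
                            bounds[:, 0], bounds[:, 1])
            alt = x_warm
        nll, x_full, ok = _reduced_minimize(objective, index, nxt, start, bounds,
                                            options, x_alt=alt)
        points.append((nxt, nll))
        if not ok:
            n_failed += 1
            value = nxt  # advance, but keep the last feasible warm start
            continue
        x_prev, x_warm = x_warm, x_full
        dj = nll - nll_here
        # refine the first crossing of the confidence threshold by bisection
        if not crossed and 2 * (nll - nll_opt) > delta >= 2 * (nll_here - nll_opt):
            crossed = True
            lo_v, lo_j, hi_v, hi_j = value, nll_here, nxt, nll
            for _ in range(options.refine_max):
                if (2 * (hi_j - lo_j) <= options.refine_gap
                        or abs(hi_v - lo_v) <= options.min_step):
                    break
                mid = 0.5 * (lo_v + hi_v)
                mj, mx, mok = _reduced_minimize(objective, index, mid, x_warm, bounds, options)
                if not mok:
                    n_failed += 1
                    break
                points.append((mid, mj))
                if 2 * (mj - nll_opt) > delta:
                    hi_v, hi_j = mid, mj
                else:
                    lo_v, lo_j, x_warm = mid, mj, mx
        if abs(dj) < options.flat_dj:
            step = min(step * 2.0, options.max_step)
        elif abs(dj) > options.steep_dj:
            step = max(step / 2.0, options.min_step)
        value, nll_here = nxt, nll
        if nll >= stop_nll:
            break
        if at_bound:
            bound_hit = True
            break
    else:
        logger.warning("profile walk hit max_points=%d before stopping", options.max_points)
    return points, bound_hit, n_failed


def profile_objective(
    objective,
    xi_hat,
    nll_opt: float,
    bounds_log10,
    index: int,
    parameter: str | None = None,
    options: ProfileOptions | None = None,
) -> ProfileResult:
    """Profile an arbitrary objective J(ξ) along coordinate ``index``.

    This is the engine behind :func:`profile_parameter`; it is exposed so
    that closed-form objectives (e.g. quadratics) can exercise the walker,
    interval location and verdicts exactly.
    """
    options = options or ProfileOptions()
    xi_hat = np.asarray(xi_hat, dtype=float)
    bounds = np.asarray(bounds_log10, dtype=float)
    if not (0 <= index < len(xi_hat)):
        raise ValueError(f"index {index} out of range for {len(xi_hat)} parameters")
    delta = delta_alpha(options.alpha)

    left, lo_hit, fail_l = _walk_direction(objective, index, xi_hat, nll_opt, bounds, -1, options)
    right, hi_hit, fail_r = _walk_direction(objective, index, xi_hat, nll_opt, bounds, +1, options)

    pts = sorted(left + [(float(xi_hat[index]), float(nll_opt))] + right)
    grid = np.array([p[0] for p in pts])
    nll = np.array([p[1] for p in pts])
    finite = nll[np.isfinite(nll)]
    nll_ref = float(min(nll_opt, finite.min()))
    if nll_ref < nll_opt - 1e-6:
        logger.warning(
            "profile of %s found a point better than the reported optimum "
            "(ΔJ=%.3g); ratios are normalized to the profile minimum",
            parameter or f"parameter {index}", nll_opt - nll_ref,
        )
    with np.errstate(over="ignore"):
        ratio = np.exp(-(nll - nll_ref))

    result = ProfileResult(
        parameter=parameter or f"p{index}",
        index=index,
        grid=grid,
        nll_profile=nll,
        ratio=ratio,
        nll_ref=nll_ref,
        nll_opt=float(nll_opt),
        xi_hat=float(xi_hat[index]),
        alpha=options.alpha,
        delta=delta,
        bounds_log10=(float(bounds[index, 0]), float(bounds[index, 1])),
        lower_bound_hit=lo_hit,
        upper_bound_hit=hi_hit,
        n_failed=fail_l + fail_r,
    )
    ci = confidence_interval(result)
    return replace(result, ci=ci, verdict=classify_identifiability(replace(result, ci=ci)))


def confidence_interval(profile: ProfileResult, alpha: float | None = None) -> ConfidenceInterval:
    """Locate the likelihood-ratio confidence interval on a profile.

    Walks outward from the profile minimum and finds where −2 log R crosses
    δ_α, interpolating linearly in −2 log R between the bracketing grid
    points.  An end that never crosses before the box bound is flagged open
    and reports the bound.  If the sub-threshold set is disconnected, the
    component containing the optimum is returned and a warning is issued.
    """
    if alpha is None:
        alpha = profile.alpha
        delta = profile.delta
    else:
        delta = delta_alpha(alpha)
    grid = profile.grid
    two = profile.two_delta_log_l()
    finite = np.isfinite(two)
    if finite.sum() < 2:
        raise ValueError("profile has fewer than two finite points")
    center = int(np.nanargmin(np.where(finite, two, np.nan)))

    def _walk(direction):
        idx = [j for j in (range(center, -1, -1) if direction < 0 else range(center, len(grid)))
               if finite[j]]
        for a, b in zip(idx, idx[1:]):
            if two[b] > delta:
                t = (delta - two[a]) / (two[b] - two[a])
                endpoint = grid[a] + t * (grid[b] - grid[a])
                beyond = [j for j in idx[idx.index(b):] if two[j] <= delta]
                if beyond:
                    warnings.warn(
                        f"profile of {profile.parameter}: sub-threshold set is "
                        "disconnected; returning the component containing the optimum",
                        stacklevel=2,
                    )
                return float(endpoint), False
        edge = grid[idx[-1]] if idx else grid[center]
        return float(edge), True

    lo, lo_open = _walk(-1)
    hi, hi_open = _walk(+1)
    return ConfidenceInterval(
        lower=10.0**lo, upper=10.0**hi,
        lower_log10=lo, upper_log10=hi,
        lower_open=lo_open, upper_open=hi_open,
        alpha=alpha, delta=delta,
    )


def classify_identifiability(profile: ProfileResult) -> str:
    """A parameter is practically identifiable iff −2 log R crosses δ_α on
    both sides of the optimum within the admissible box."""
    ci = profile.ci if profile.ci is not None else confidence_interval(profile)
    return NON_IDENTIFIABLE if (ci.lower_open or ci.upper_open) else IDENTIFIABLE


# ---------------------------------------------------------------------------
# PDE-model front ends


def _model_objective(fit: FitResult, data: ImageSeries, ctx: ModelContext):
    template = fit.theta_hat

    def objective(xi):
        return objective_in_log_space(xi, data, ctx, template, fit.profile_noise)

    return objective


def profile_parameter(
    parameter: str | int,
    fit: FitResult,
    data: ImageSeries,
    ctx: ModelContext,
    options: ProfileOptions | None = None,
) -> ProfileResult:
    """Profile one kinetic parameter of a fitted model.

    ``parameter`` is a name from ``("D", "alpha", "k1", "km1", "gamma")`` or
    its index.  Inner re-optimizations run under the same bounds and noise
    handling as the original fit, warm-started from the previous profile
    point.
    """
    index = KINETIC_NAMES.index(parameter) if isinstance(parameter, str) else int(parameter)
    name = KINETIC_NAMES[index]
    return profile_objective(
        _model_objective(fit, data, ctx),
        fit.xi_hat,
        fit.nll_opt,
        fit.theta_hat.log10_bounds,
        index,
        parameter=name,
        options=options,
    )


def profile_all(
    fit: FitResult,
    data: ImageSeries,
    ctx: ModelContext,
    options: ProfileOptions | None = None,
    parameters=KINETIC_NAMES,
) -> dict[str, ProfileResult]:
    """Profile several (default: all five) kinetic parameters."""
    return {name: profile_parameter(name, fit, data, ctx, options=options)
            for name in parameters}


def hessian_approximation(
    objective,
    xi_hat,
    alpha: float = 0.98,
    step: float = 0.02,
    parameters: tuple[str, ...] | None = None,
    nll_opt: float | None = None,
) -> LocalApproximation:
    """Central-second-difference Hessian of an objective and the implied
    asymptotic confidence intervals (generic engine)."""
    xi = np.asarray(xi_hat, dtype=float)
    d = len(xi)
    delta = delta_alpha(alpha)
    f0 = float(objective(xi)) if nll_opt is None else float(nll_opt)

    def f(x):
        return float(objective(x))

    h = step
    hess = np.empty((d, d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        hess[i, i] = (f(xi + ei) - 2.0 * f0 + f(xi - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                f(xi + ei + ej) - f(xi + ei - ej) - f(xi - ei + ej) + f(xi - ei - ej)
            ) / (4.0 * h**2)

    reliable = True
    eig = np.linalg.eigvalsh(hess)
    if eig.min() <= 0:
        warnings.warn(
            "Hessian at the optimum is not positive definite; asymptotic "
            "intervals are unreliable",
            stacklevel=2,
        )
        reliable = False
        cov = np.linalg.pinv(hess)
    else:
        cov = np.linalg.inv(hess)
    var = np.diag(cov).copy()
    var[var <= 0] = np.nan
    half = np.sqrt(delta * var)
    ci_log10 = np.column_stack([xi - half, xi + half])
    names = tuple(parameters) if parameters else tuple(f"p{i}" for i in range(d))
    return LocalApproximation(
        hessian=hess,
        xi_hat=xi,
        nll_opt=f0,
        alpha=alpha,
        delta=delta,
        parameters=names,
        half_widths_log10=half,
        ci_log10=ci_log10,
        ci=10.0**ci_log10,
        reliable=reliable,
    )


def local_approximation(
    fit: FitResult,
    data: ImageSeries,
    ctx: ModelContext,
    alpha: float = 0.98,
    step: float = 0.02,
) -> LocalApproximation:
    """Hessian-based quadratic approximation of the fitted model's J at θ̂,
    for comparison with the profiles (the classical asymptotic intervals)."""
    return hessian_approximation(
        _model_objective(fit, data, ctx),
        fit.xi_hat,
        alpha=alpha,
        step=step,
        parameters=KINETIC_NAMES,
        nll_opt=None,  # re-evaluate at xi_hat for a consistent stencil center
    )
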