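"""Maximum-likelihood estimation by multi-start bound-constrained optimization.

The five kinetic parameters are optimized on a log10 scale, which turns the
positivity constraints and the multiplicative box [10⁻², 10¹]⁵ into the cube
[−2, 1]⁵ and gives all parameters comparable scales.  The noise variance σ²
is profiled analytically inside the objective; the background offset b is
held at its known value by default (it can be opened by fitting a template
with a different b).

Starts are the box center plus a seeded Latin-hypercube sample drawn from a
fixed pool, so start sets are nested: increasing ``n_starts`` only adds
starts and can never lose the previous best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .errors import EstimationFailure
from .likelihood import ModelContext, neg_log_likelihood
from .model import KINETIC_NAMES, ModelParameters
from .observation import ImageSeries

logger = logging.getLogger(__name__)

#: size of the fixed Latin-hypercube start pool (prefix-nested start sets)
_START_POOL = 64


@dataclass(frozen=True)
class StartRecord:
    """One local optimization: where it started, where it ended, how."""

    x0: np.ndarray
    x_opt: np.ndarray
    nll: float
    success: bool
    n_eval: int
    message: str


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start maximum-likelihood fit."""

    theta_hat: ModelParameters
    nll_opt: float
    starts: tuple[StartRecord, ...]
    n_converged: int
    sigma2_hat: float | None = None
    profile_noise: bool = True

    @property
    def xi_hat(self) -> np.ndarray:
        """The optimum in log10 kinetic coordinates."""
        return self.theta_hat.log10_kinetics

    def summary(self) -> dict:
        return {
            "theta_hat": dict(zip(KINETIC_NAMES, self.theta_hat.kinetics.tolist())),
            "log10_theta_hat": dict(zip(KINETIC_NAMES, self.xi_hat.tolist())),
            "nll": self.nll_opt,
            "sigma2_hat": self.sigma2_hat,
            "n_starts": len(self.starts),
            "n_converged": self.n_converged,
        }


def objective_in_log_space(
    xi,
    data: ImageSeries,
    ctx: ModelContext,
    template: ModelParameters,
    profile_noise: bool = True,
) -> float:
    """J(10^ξ): the negative log-likelihood composed with exponentiation.

    No rescaling of J is applied — only the change of variables.  Returns
    +inf at infeasible points (failed forward solves).
    """
    params = template.with_log10_kinetics(xi)
    return neg_log_likelihood(params, data, ctx, profile_noise=profile_noise).nll


def draw_starts(bounds_log10: np.ndarray, n_starts: int, seed: int) -> np.ndarray:
    """Box center plus the first ``n_starts - 1`` points of a seeded
    Latin-hypercube pool, mapped into the log10 box; shape (n_starts, 5)."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo, hi = bounds_log10[:, 0], bounds_log10[:, 1]
    center = 0.5 * (lo + hi)
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    pool = qmc.scale(sampler.random(_START_POOL), lo, hi)
    return np.vstack([center, pool[: n_starts - 1]])


def _minimize(fun, x0, bounds, method, tol, max_iter):
    if method == "hybrid":
        # quasi-Newton descent with deep memory (the k1/km1/gamma ridge is
        # ill-conditioned) followed by a small-simplex polish that mops up
        # the last fraction of a nat the line searches leave behind
        r1 = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                               options={"maxiter": max_iter, "ftol": tol,
                                        "eps": 1e-5, "maxcor": 20})
        simplex = np.vstack([r1.x] + [np.clip(r1.x + 0.02 * e,
                                              [b[0] for b in bounds],
                                              [b[1] for b in bounds])
                             for e in np.eye(len(r1.x))])
        r2 = optimize.minimize(fun, r1.x, method="Nelder-Mead", bounds=bounds,
                               options={"maxiter": min(400, 4 * max_iter),
                                        "fatol": 1e-5, "xatol": 1e-5,
                                        "initial_simplex": simplex})
        best = r2 if r2.fun <= r1.fun else r1
        best.nfev = r1.nfev + r2.nfev
        return best
    options: dict = {"maxiter": max_iter}
    kwargs: dict = {"method": method, "bounds": bounds, "options": options}
    if method == "L-BFGS-B":
        options.update({"ftol": tol, "eps": 1e-5, "maxcor": 20})
    elif method == "Powell":
        options.update({"ftol": tol, "xtol": 1e-7})
    elif method == "Nelder-Mead":
        options.update({"fatol": tol, "xatol": 1e-6})
    else:
        kwargs["tol"] = tol
    return optimize.minimize(fun, x0, **kwargs)


def fit_mle(
    data: ImageSeries,
    ctx: ModelContext,
    template: ModelParameters | None = None,
    n_starts: int = 10,
    seed: int = 0,
    method: str = "hybrid",
    tol: float = 1e-9,
    max_iter: int = 500,
    profile_noise: bool = True,
) -> FitResult:
    """Fit the five kinetic parameters to an image series.

    Parameters
    ----------
    template : ModelParameters, optional
        Carries the bounds, the offset b and (if ``profile_noise=False``)
        the noise variance; kinetic entries are placeholders.  Defaults to
        the benchmark truth values purely as a bounds/offset carrier.
    n_starts : int
        Local optimizations to run: the box center plus ``n_starts - 1``
        Latin-hypercube points (nested as ``n_starts`` grows).
    seed : int
        Seed for the start sampler; same seed → identical FitResult.
    method : str
        Any bound-constrained ``scipy.optimize.minimize`` method;
        quasi-Newton with finite differences by default.

    Raises
    ------
    EstimationFailure
        If no start produced a finite objective value.
    """
    if template is None:
        from .model import default_true_parameters

        template = default_true_parameters()
    bounds_log10 = template.log10_bounds
    bounds = [tuple(row) for row in bounds_log10]

    def fun(xi):
        return objective_in_log_space(xi, data, ctx, template, profile_noise)

    starts = draw_starts(bounds_log10, n_starts, seed)
    records = []
    for x0 in starts:
        res = _minimize(fun, x0, bounds, method, tol, max_iter)
        records.append(
            StartRecord(
                x0=x0.copy(),
                x_opt=np.asarray(res.x, dtype=float),
                nll=float(res.fun),
                success=bool(res.success) and np.isfinite(res.fun),
                n_eval=int(getattr(res, "nfev", -1)),
                message=str(res.message),
            )
        )

    finite = [r for r in records if np.isfinite(r.nll)]
    if not finite:
        raise EstimationFailure(
            "all optimization starts failed; statuses: "
            + "; ".join(r.message for r in records)
        )
    best_nll = min(r.nll for r in finite)
    # ties broken toward the start whose optimum is nearest the box center
    center = 0.5 * (bounds_log10[:, 0] + bounds_log10[:, 1])
    best = min(
        (r for r in finite if r.nll <= best_nll + 1e-12),
        key=lambda r: float(np.linalg.norm(r.x_opt - center)),
    )
    theta_hat = template.with_log10_kinetics(best.x_opt)
    obj = neg_log_likelihood(theta_hat, data, ctx, profile_noise=profile_noise)
    if obj.sigma2_hat is not None:
        theta_hat = theta_hat.replace(sigma2=obj.sigma2_hat)
    n_converged = sum(r.success for r in records)
    if n_converged == 0:
        logger.warning("no start reported formal convergence; using best finite value")
    return FitResult(
        theta_hat=theta_hat,
        nll_opt=best.nll,
        starts=tuple(records),
        n_converged=n_converged,
        sigma2_hat=obj.sigma2_hat,
        profile_noise=profile_noise,
    )
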