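"""Log-normal likelihood of an image time series under the model.

For observed intensities ȳ_{k,i} and model predictions y_{k,i}(θ) the data
are modelled as ȳ = ε y with ε ~ LogNormal(0, σ²), so each observation has
the log-normal density with log-scale location log y and variance σ².  The
negative log-likelihood is

    J(θ) = Σ_{k,i} [ log(√(2π) σ ȳ_{k,i}) + (log ȳ_{k,i} − log y_{k,i}(θ))² / (2σ²) ]

The noise variance has a closed-form inner maximizer at fixed kinetics,
σ̂² = mean of squared log-residuals, so σ² never needs numeric optimization
(:func:`profile_sigma2`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import DomainGrid
from .model import DEFAULT_ATOL, DEFAULT_RTOL, ModelParameters, simulate
from .observation import ImageSeries, observe
from .sources import SourceMap
from .errors import SolverFailure

logger = logging.getLogger(__name__)

#: lower guard for the profiled noise variance (exact-fit degeneracy)
SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelContext:
    """Everything besides the parameters needed to predict an image series:
    the grid, the source geometry and the integrator tolerances."""

    grid: DomainGrid
    source: SourceMap
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    method: str = "BDF"


@dataclass(frozen=True)
class ObjectiveValue:
    """Value of the negative log-likelihood and its ingredients.

    ``nll`` is +inf (with ``residuals`` and ``sigma2_hat`` None) when the
    forward solve failed, so optimizers treat the point as infeasible.
    """

    nll: float
    residuals: np.ndarray | None = None
    sigma2_hat: float | None = None


def lognormal_nll(y_obs, y_pred, sigma2: float) -> float:
    """Negative log-density of observations under the multiplicative
    log-normal noise model, summed over all entries.

    Closed form per observation: log(√(2π)·σ·ȳ) + (log ȳ − log y)²/(2σ²).
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.size == 0:
        raise ValueError("no observations")
    if np.any(y_obs <= 0):
        raise ValueError("observed intensities must be strictly positive")
    if np.any(y_pred <= 0):
        raise ValueError("predicted intensities must be strictly positive")
    if not (sigma2 > 0):
        raise ValueError(f"sigma2 must be strictly positive, got {sigma2!r}")
    r = np.log(y_obs) - np.log(y_pred)
    return float(
        y_obs.size * 0.5 * np.log(2.0 * np.pi * sigma2)
        + np.sum(np.log(y_obs))
        + np.sum(r * r) / (2.0 * sigma2)
    )


def profile_sigma2(residuals, floor: float = SIGMA2_FLOOR) -> float:
    """Closed-form maximizer of the likelihood over σ² at fixed kinetics:
    the mean squared log-residual, guarded below by ``floor``."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residual list")
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals must be finite")
    return max(float(np.mean(r * r)), floor)


def predict(params: ModelParameters, data: ImageSeries, ctx: ModelContext) -> ImageSeries:
    """Model prediction of the clean image series at the data's times."""
    traj = simulate(params, ctx.source, ctx.grid, data.times,
                    rtol=ctx.rtol, atol=ctx.atol, method=ctx.method)
    return observe(traj, data.layout, params.b)


def neg_log_likelihood(
    params: ModelParameters,
    data: ImageSeries,
    ctx: ModelContext,
    profile_noise: bool = False,
) -> ObjectiveValue:
    """Evaluate J(θ) for a parameter vector against an image dataset.

    With ``profile_noise=True`` the noise variance is replaced by its
    closed-form maximizer σ̂² (mean squared log-residual); otherwise
    ``params.sigma2`` is used.  A failed forward solve yields a +inf
    sentinel rather than an exception, so optimizers can continue.
    """
    if np.any(data.values <= 0):
        raise ValueError("data intensities must be strictly positive")
    try:
        pred = predict(params, data, ctx)
    except SolverFailure as exc:
        logger.warning("forward solve failed, returning +inf objective: %s", exc)
        return ObjectiveValue(nll=np.inf)
    residuals = np.log(data.values) - np.log(pred.values)
    sigma2 = profile_sigma2(residuals) if profile_noise else params.sigma2
    nll = lognormal_nll(data.values, pred.values, sigma2)
    return ObjectiveValue(nll=nll, residuals=residuals,
                          sigma2_hat=sigma2 if profile_noise else None)
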