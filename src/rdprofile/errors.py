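"""Exception hierarchy for rdprofile.

All package-specific errors derive from :class:`RDProfileError` so callers can
catch everything from this package with one handler.  ``SolverFailure`` carries
the offending parameter vector so optimizers can treat the point as infeasible
instead of crashing.
"""

from __future__ import annotations


class RDProfileError(Exception):
    """Base class for all rdprofile errors."""


class GeometryError(RDProfileError, ValueError):
    """Invalid source geometry (degenerate segment, empty indicator, ...)."""


class ResolutionError(RDProfileError, ValueError):
    """Pixel layout incompatible with the grid (pixel below cell size or
    misaligned with cell boundaries)."""


class SolverFailure(RDProfileError, RuntimeError):
    """The time integrator failed to meet its tolerances.

    Attributes
    ----------
    params : ModelParameters or None
        The parameter vector at which the solve failed, so the caller can log
        or penalise it.
    """

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params


class EstimationFailure(RDProfileError, RuntimeError):
    """Every optimization start failed."""


class FormatError(RDProfileError, ValueError):
    """Malformed on-disk artifact (missing sidecar, shape mismatch, ...)."""


class ConfigError(RDProfileError, ValueError):
    """Invalid or unknown configuration keys/values."""
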