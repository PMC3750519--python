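"""Source geometry for the release term Q.

The built-in worked example mimics a branching lymphatic vessel: a y-shaped
union of three thickened line segments (stem, left branch, right branch) that
releases signaling protein at constant rate.  ``build_y_source`` rasterizes
the shape to a binary indicator on a :class:`~rdprofile.grid.DomainGrid`; an
optional smooth-edge variant (a Gaussian falloff of the distance to the
shape) exists for numerical studies where a discontinuous source would limit
the spatial convergence order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .grid import DomainGrid

# canonical default geometry of the vessel branch (all coordinates in Ω units)
DEFAULT_STEM_BASE = (0.5, 0.05)
DEFAULT_BRANCH_POINT = (0.5, 0.45)
DEFAULT_TIP_LEFT = (0.25, 0.95)
DEFAULT_TIP_RIGHT = (0.75, 0.95)
DEFAULT_HALF_WIDTH = 0.05


@dataclass(frozen=True)
class SourceMap:
    """Spatial release profile Q on the grid.

    ``values`` is an ``(nx, nx)`` array in [0, 1].  For the standard binary
    vessel indicator every entry is exactly 0 or 1; smooth-edged variants
    (used in grid-convergence studies) take intermediate values.
    """

    values: np.ndarray
    grid: DomainGrid

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.grid.nx, self.grid.nx):
            raise GeometryError(
                f"source values shape {v.shape} does not match grid "
                f"({self.grid.nx}, {self.grid.nx})"
            )
        if not np.all(np.isfinite(v)) or v.min() < 0 or v.max() > 1:
            raise GeometryError("source values must be finite and in [0, 1]")
        if v.max() <= 0:
            raise GeometryError("source is empty: no node receives any release")

    @property
    def is_binary(self) -> bool:
        return bool(np.all((self.values == 0) | (self.values == 1)))

    @property
    def n_active(self) -> int:
        """Number of nodes with a strictly positive release."""
        return int(np.count_nonzero(self.values))


def segment_distance(px, py, a, b) -> np.ndarray:
    """Euclidean distance from points ``(px, py)`` to the segment ``a``–``b``.

    Vectorized over ``px``/``py``.  Raises :class:`GeometryError` for a
    degenerate (zero-length) segment.
    """
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    vx, vy = bx - ax, by - ay
    length2 = vx * vx + vy * vy
    if length2 == 0.0:
        raise GeometryError(f"degenerate segment: both endpoints at {a}")
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / length2, 0.0, 1.0)
    return np.hypot(px - (ax + t * vx), py - (ay + t * vy))


def _check_point(name, pt, extent):
    x, y = float(pt[0]), float(pt[1])
    if not (0.0 <= x <= extent and 0.0 <= y <= extent):
        raise GeometryError(f"{name}={pt} lies outside the domain [0, {extent}]²")


def build_y_source(
    grid: DomainGrid,
    stem_base=DEFAULT_STEM_BASE,
    branch_point=DEFAULT_BRANCH_POINT,
    tip_left=DEFAULT_TIP_LEFT,
    tip_right=DEFAULT_TIP_RIGHT,
    half_width: float = DEFAULT_HALF_WIDTH,
    soft_edge: float | None = None,
) -> SourceMap:
    """Rasterize a y-shaped vessel source onto the grid.

    A node is active iff its distance to the union of the three segments
    (stem_base→branch_point, branch_point→tip_left, branch_point→tip_right)
    is at most ``half_width``.

    Parameters
    ----------
    half_width : float
        Half the thickness of the vessel, in domain units.
    soft_edge : float, optional
        If given, instead of a sharp cut the indicator decays smoothly as
        ``exp(-((d - half_width)⁺ / soft_edge)² / 2)`` with ``d`` the distance
        to the segments.  Useful when a discontinuous source would limit the
        convergence order of the spatial discretization.
    """
    if not (half_width > 0):
        raise GeometryError(f"half_width must be positive, got {half_width!r}")
    for name, pt in (
        ("stem_base", stem_base),
        ("branch_point", branch_point),
        ("tip_left", tip_left),
        ("tip_right", tip_right),
    ):
        _check_point(name, pt, grid.extent)
    for name, pt in (("stem_base", stem_base), ("tip_left", tip_left), ("tip_right", tip_right)):
        if tuple(map(float, pt)) == tuple(map(float, branch_point)):
            raise GeometryError(f"branch_point coincides with {name}")

    X, Y = grid.mesh()
    d = np.minimum.reduce(
        [
            segment_distance(X, Y, stem_base, branch_point),
            segment_distance(X, Y, branch_point, tip_left),
            segment_distance(X, Y, branch_point, tip_right),
        ]
    )
    if soft_edge is None:
        values = (d <= half_width).astype(float)
        if values.max() <= 0:
            raise GeometryError(
                "half_width too small: no grid node falls inside the source "
                f"(min distance {d.min():.4g} > half_width {half_width:.4g})"
            )
    else:
        if not (soft_edge > 0):
            raise GeometryError(f"soft_edge must be positive, got {soft_edge!r}")
        excess = np.maximum(d - half_width, 0.0)
        values = np.exp(-0.5 * (excess / soft_edge) ** 2)
    return SourceMap(values=values, grid=grid)


def gaussian_bump_source(grid: DomainGrid, center=(0.5, 0.5), radius: float = 0.1) -> SourceMap:
    """Smooth radially symmetric source ``exp(-|x - center|² / (2 radius²))``.

    Infinitely differentiable in space; intended for discretization-order
    studies where the binary vessel indicator would dominate the error.
    """
    if not (radius > 0):
        raise GeometryError(f"radius must be positive, got {radius!r}")
    _check_point("center", center, grid.extent)
    X, Y = grid.mesh()
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
    return SourceMap(values=np.exp(-0.5 * r2 / radius**2), grid=grid)
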