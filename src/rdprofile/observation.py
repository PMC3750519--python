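"""Observation model: from state fields to pixel intensities.

A microscopy image is modelled as the area integral of the stained species
over each pixel plus a constant background offset:

    y_{k,i} = b + ∫_{A_i} c(t_k, x) dx

Pixels are axis-aligned rectangles tiling the domain; the integral is a
midpoint quadrature over the grid cells inside the pixel (exact for fields
that are piecewise constant per cell).  Pixels must align with grid-cell
boundaries so that no interpolation ambiguity arises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, ResolutionError
from .grid import DomainGrid
from .model import StateTrajectory


@dataclass(frozen=True)
class PixelLayout:
    """A rows × cols tiling of the domain into equal rectangular pixels.

    Pixels are raster-ordered row-major: pixel ``i`` covers row ``i // cols``
    (the y band) and column ``i % cols`` (the x band), with row 0 at the
    bottom (y = 0).
    """

    rows: int
    cols: int
    extent: float = 1.0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")

    @property
    def M(self) -> int:
        """Number of pixels per image."""
        return self.rows * self.cols

    @property
    def pixel_area(self) -> float:
        return self.extent * self.extent / self.M

    @property
    def areas(self) -> np.ndarray:
        return np.full(self.M, self.pixel_area)

    def pixel_regions(self) -> list[tuple[float, float, float, float]]:
        """Rectangles ``(x0, y0, x1, y1)`` in raster (row-major) order."""
        wx = self.extent / self.cols
        wy = self.extent / self.rows
        return [
            (c * wx, r * wy, (c + 1) * wx, (r + 1) * wy)
            for r in range(self.rows)
            for c in range(self.cols)
        ]


@dataclass(frozen=True)
class ImageSeries:
    """Pixel intensities for a time series of images.

    ``values`` has shape ``(N, M)``: ``values[k, i]`` is the intensity of
    pixel ``i`` (raster order) at acquisition time ``times[k]``.  ``noisy``
    marks whether the values carry measurement noise; noisy intensities must
    be strictly positive (log-normal support).
    """

    times: np.ndarray
    values: np.ndarray
    layout: PixelLayout
    noisy: bool = False

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1:
            raise FormatError("times must be 1D")
        if values.shape != (times.size, self.layout.M):
            raise FormatError(
                f"values shape {values.shape} does not match "
                f"(N={times.size}, M={self.layout.M})"
            )
        if not np.all(np.isfinite(values)):
            raise FormatError("image values must be finite")
        if self.noisy and values.min() <= 0:
            raise FormatError(
                "noisy image series contains non-positive intensities "
                "(outside log-normal support)"
            )

    @property
    def N(self) -> int:
        return int(self.times.size)

    @property
    def M(self) -> int:
        return self.layout.M

    def as_images(self) -> np.ndarray:
        """Values reshaped to ``(N, rows, cols)`` image stacks."""
        return self.values.reshape(self.N, self.layout.rows, self.layout.cols)


def make_tiling_layout(grid: DomainGrid, rows: int, cols: int) -> PixelLayout:
    """Tile the domain into rows × cols equal pixels aligned to grid cells.

    Each pixel must cover a whole number of grid cells per axis (at least
    one), otherwise a :class:`ResolutionError` is raised.
    """
    if rows < 1 or cols < 1:
        raise ResolutionError("rows and cols must be >= 1")
    if grid.nx % rows != 0 or grid.nx % cols != 0:
        raise ResolutionError(
            f"a {rows}x{cols} pixel tiling does not align with a {grid.nx}x{grid.nx} "
            "grid: nx must be divisible by both rows and cols"
        )
    return PixelLayout(rows=rows, cols=cols, extent=grid.extent)


def integrate_field(field: np.ndarray, layout: PixelLayout, grid: DomainGrid) -> np.ndarray:
    """Midpoint quadrature of a ``(nx, nx)`` field over each pixel.

    Returns the ``M`` per-pixel integrals in raster order.  This is the
    quadrature backbone of :func:`observe` and is also handy for injecting
    analytic fields in tests.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.nx, grid.nx):
        raise ValueError(f"field shape {field.shape} != grid ({grid.nx}, {grid.nx})")
    if grid.nx % layout.rows != 0 or grid.nx % layout.cols != 0:
        raise ResolutionError("pixel layout does not align with the grid")
    by = grid.nx // layout.rows
    bx = grid.nx // layout.cols
    blocks = field.reshape(layout.rows, by, layout.cols, bx).sum(axis=(1, 3))
    return (blocks * grid.cell_area).ravel()


def observe(traj: StateTrajectory, layout: PixelLayout, b: float) -> ImageSeries:
    """Apply the observation map to a trajectory: ``y = b + ∫_pixel c dx``.

    The observable is the immobilized complex ``c`` (what the staining in
    the motivating experiment binds to).
    """
    if b < 0:
        raise ValueError(f"offset b must be non-negative, got {b!r}")
    values = np.stack([b + integrate_field(traj.c[k], layout, traj.grid)
                       for k in range(traj.times.size)])
    return ImageSeries(times=traj.times, values=values, layout=layout, noisy=False)
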