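"""Uniform cell-centered discretization of the square domain Ω = [0, 1]².

The grid places one node at the center of each of the ``nx × nx`` cells, so
all nodes lie strictly inside the domain and the no-flux (Neumann) boundary
condition has a natural ghost-cell reflection.  Fields on the grid are stored
as ``(nx, nx)`` arrays indexed ``[iy, ix]`` (row = y, column = x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DomainGrid:
    """Uniform cell-centered grid on Ω = [0, extent]².

    Parameters
    ----------
    nx : int
        Number of cells (= nodes) per axis; at least 4.
    extent : float
        Side length of the square domain. The model is formulated on the unit
        square, so this defaults to 1.0 and rarely changes.
    """

    nx: int
    extent: float = 1.0

    def __post_init__(self):
        if int(self.nx) != self.nx or self.nx < 4:
            raise ValueError(f"nx must be an integer >= 4, got {self.nx!r}")
        if not (self.extent > 0):
            raise ValueError(f"extent must be positive, got {self.extent!r}")

    @property
    def dx(self) -> float:
        """Cell width, extent / nx."""
        return self.extent / self.nx

    @property
    def n_nodes(self) -> int:
        return self.nx * self.nx

    @property
    def cell_centers(self) -> np.ndarray:
        """1D coordinates of cell centers along one axis."""
        return (np.arange(self.nx) + 0.5) * self.dx

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` coordinate arrays of shape ``(nx, nx)``.

        ``X[iy, ix]`` is the x-coordinate of node ``(iy, ix)`` and likewise
        for ``Y``; both lie strictly inside the domain.
        """
        c = self.cell_centers
        return np.meshgrid(c, c, indexing="xy")

    @property
    def cell_area(self) -> float:
        return self.dx * self.dx
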