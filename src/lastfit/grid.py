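"""Regular height grids in millimetres.

A :class:`SurfaceGrid` is a lattice of heights ``z[i, j]`` where index ``i``
runs along the x axis (``x_coords``) and ``j`` along the y axis
(``y_coords``).  The same container carries a last lower surface and a
footprint topography.  Patch fitting requires both lattice dimensions to be
``5k + 1`` so the grid splits into 6x6-point blocks that share border
rows/columns with their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .exceptions import GridError


def _as_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise GridError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class SurfaceGrid:
    """Heights (mm) on a regular x-y lattice.

    Parameters
    ----------
    heights : ndarray, shape (nx, ny)
        Surface heights in mm; ``heights[i, j]`` sits at
        ``(x_coords[i], y_coords[j])``.
    x_coords, y_coords : ndarray
        Strictly increasing lattice positions in mm.
    """

    heights: np.ndarray
    x_coords: np.ndarray
    y_coords: np.ndarray

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.x_coords = _as_1d(self.x_coords, "x_coords")
        self.y_coords = _as_1d(self.y_coords, "y_coords")
        if self.heights.ndim != 2:
            raise GridError(f"heights must be 2-D, got shape {self.heights.shape}")
        if self.heights.shape != (self.x_coords.size, self.y_coords.size):
            raise GridError(
                f"heights shape {self.heights.shape} does not match "
                f"({self.x_coords.size}, {self.y_coords.size}) coordinates"
            )
        if not np.all(np.isfinite(self.heights)):
            raise GridError("heights contain non-finite values")
        for name, c in (("x_coords", self.x_coords), ("y_coords", self.y_coords)):
            if c.size > 1 and not np.all(np.diff(c) > 0):
                raise GridError(f"{name} must be strictly increasing")

    # -- lattice structure -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def is_patchable(self) -> bool:
        """True when both dimensions are congruent to 1 (mod 5) and >= 6."""
        nx, ny = self.shape
        return nx >= 6 and ny >= 6 and nx % 5 == 1 and ny % 5 == 1

    def require_patchable(self) -> None:
        if not self.is_patchable():
            raise GridError(
                f"grid shape {self.shape} is not 5k+1 per axis; resample the grid "
                "(see SurfaceGrid.resample_to) before patch fitting"
            )

    @property
    def patch_layout(self) -> tuple[int, int]:
        """Number of 6x6 patches along x and y."""
        self.require_patchable()
        nx, ny = self.shape
        return (nx - 1) // 5, (ny - 1) // 5

    def patch_block(self, r: int, t: int) -> np.ndarray:
        """View of the 6x6 height block of patch ``(r, t)``."""
        self.require_patchable()
        return self.heights[5 * r : 5 * r + 6, 5 * t : 5 * t + 6]

    def patch_coords(self, r: int, t: int) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.x_coords[5 * r : 5 * r + 6],
            self.y_coords[5 * t : 5 * t + 6],
        )

    # -- derived grids -----------------------------------------------------

    def with_heights(self, heights: np.ndarray) -> "SurfaceGrid":
        return SurfaceGrid(np.asarray(heights, dtype=float), self.x_coords.copy(), self.y_coords.copy())

    def copy(self) -> "SurfaceGrid":
        return self.with_heights(self.heights.copy())

    def resample_to(self, x_new, y_new) -> "SurfaceGrid":
        """Bilinear resampling onto a new lattice (used to register two grids)."""
        x_new = _as_1d(x_new, "x_new")
        y_new = _as_1d(y_new, "y_new")
        interp = RegularGridInterpolator(
            (self.x_coords, self.y_coords), self.heights,
            method="linear", bounds_error=False, fill_value=None,
        )
        xx, yy = np.meshgrid(x_new, y_new, indexing="ij")
        z = interp(np.stack([xx.ravel(), yy.ravel()], axis=1)).reshape(x_new.size, y_new.size)
        return SurfaceGrid(z, x_new, y_new)

    def resample_shape(self, nx: int, ny: int) -> "SurfaceGrid":
        """Resample onto a uniform lattice of the given shape over the same extent."""
        return self.resample_to(
            np.linspace(self.x_coords[0], self.x_coords[-1], nx),
            np.linspace(self.y_coords[0], self.y_coords[-1], ny),
        )

    def extent(self) -> tuple[float, float]:
        """(x extent, y extent) of the lattice outline, mm."""
        return (
            float(self.x_coords[-1] - self.x_coords[0]),
            float(self.y_coords[-1] - self.y_coords[0]),
        )
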