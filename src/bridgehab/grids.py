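"""Shared raster containers.

All rasters in this package live on a :class:`GridDef`: a regular grid of
square cells in a projected (metric) coordinate system, row 0 at the top
edge (raster convention), x increasing east and y increasing north.
``x_origin``/``y_origin`` are the coordinates of the grid's north-west
corner; cell ``(r, c)`` has its center at
``(x_origin + (c + 0.5) * cell_size, y_origin - (r + 0.5) * cell_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridDef:
    """Geometry of a regular square-celled raster."""

    x_origin: float
    y_origin: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_origin - self.n_rows * self.cell_size

    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing point (x, y)."""
        c = int(np.floor((x - self.x_origin) / self.cell_size))
        r = int(np.floor((self.y_origin - y) / self.cell_size))
        return r, c

    def contains_point(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.x_origin)
            & (x <= self.x_max)
            & (y <= self.y_origin)
            & (y >= self.y_min)
        )

    def covers(self, other: "GridDef") -> bool:
        return (
            other.x_origin >= self.x_origin
            and other.x_max <= self.x_max
            and other.y_origin <= self.y_origin
            and other.y_min >= self.y_min
        )

    def window_of(self, sub: "GridDef") -> tuple[int, int]:
        """Row/col offset of an aligned subgrid; raises if misaligned."""
        if sub.cell_size != self.cell_size:
            raise ValueError("cell sizes differ")
        dc = (sub.x_origin - self.x_origin) / self.cell_size
        dr = (self.y_origin - sub.y_origin) / self.cell_size
        if abs(dc - round(dc)) > 1e-9 or abs(dr - round(dr)) > 1e-9:
            raise ValueError("subgrid is not aligned to the parent lattice")
        r0, c0 = int(round(dr)), int(round(dc))
        if r0 < 0 or c0 < 0 or r0 + sub.n_rows > self.n_rows or c0 + sub.n_cols > self.n_cols:
            raise ValueError("subgrid extends beyond the parent grid")
        return r0, c0


@dataclass
class PDFGrid:
    """Utilization distribution on a raster.

    ``density`` holds the probability density (m^-2) at each cell center;
    ``cell_mass`` is density times cell area, i.e. an approximate
    probability per cell.  After normalization the masses sum to 1.
    """

    grid: GridDef
    density: np.ndarray
    prenorm_mass: float | None = None  # total mass before renormalization

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("density shape does not match grid definition")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")

    @property
    def cell_mass(self) -> np.ndarray:
        return self.density * self.grid.cell_area

    @property
    def total_mass(self) -> float:
        return float(self.cell_mass.sum())

    def normalized(self) -> "PDFGrid":
        total = self.total_mass
        if total <= 0:
            raise ValueError("cannot normalize a zero PDF")
        return PDFGrid(self.grid, self.density / total)


@dataclass
class LandCoverGrid:
    """Categorical land-cover raster with a code -> label map."""

    grid: GridDef
    class_code: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.class_code = np.asarray(self.class_code)
        if not np.issubdtype(self.class_code.dtype, np.integer):
            raise ValueError("land-cover codes must be integers")
        if self.class_code.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("class_code shape does not match grid definition")

    def codes_present(self) -> np.ndarray:
        return np.unique(self.class_code)

    def crop(self, sub: GridDef) -> "LandCoverGrid":
        """Extract the window matching an aligned subgrid."""
        r0, c0 = self.grid.window_of(sub)
        return LandCoverGrid(
            sub,
            self.class_code[r0 : r0 + sub.n_rows, c0 : c0 + sub.n_cols].copy(),
            dict(self.class_names),
        )
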