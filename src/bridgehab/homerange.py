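"""Volume-contour home ranges from a utilization distribution.

The home range at level p is the smallest set of raster cells whose
center densities exceed a common threshold while jointly holding at least
a fraction p of the PDF volume: cells are ranked by density, accumulated
until the level is reached, and every cell tied with the last included
density enters as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridDef, PDFGrid


@dataclass
class HomeRange:
    """Cells inside the volume contour of a PDF at a given level."""

    grid: GridDef
    mask: np.ndarray
    threshold: float
    level: float = 0.95

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("mask shape does not match grid definition")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.grid.cell_area / 1e6


def volume_contour(pdf: PDFGrid, level: float = 0.95) -> HomeRange:
    """Extract the minimal density-threshold cell set holding ``level`` mass.

    The PDF must be normalized (total mass within [0.9, 1.1]).  Ties at
    the threshold density are all included, so with exactly uniform
    densities the contour is the whole support.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    total = pdf.total_mass
    if not 0.9 <= total <= 1.1:
        raise ValueError(f"PDF is not normalized (total mass {total:.4f})")

    dens = pdf.density.ravel()
    mass = pdf.cell_mass.ravel() / total
    order = np.argsort(dens, kind="stable")[::-1]
    cum = np.cumsum(mass[order])
    k = int(np.searchsorted(cum, level, side="left"))
    k = min(k, order.size - 1)
    threshold = float(dens[order[k]])
    mask = pdf.density >= threshold
    return HomeRange(grid=pdf.grid, mask=mask, threshold=threshold, level=level)


def home_range_area(hr: HomeRange) -> float:
    """Home-range area in km^2: masked-cell count times cell area."""
    return hr.area_km2
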