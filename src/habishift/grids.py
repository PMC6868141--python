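"""Grid geometry for the raster layers every stage operates on.

Two modes are supported.  The default "planar" mode treats the grid as an
equal-area projection: every cell is a square of ``cell_size`` km on a side,
so areas are counts times ``cell_size**2`` and distances are Euclidean in km.
A "geographic" mode interprets ``cell_size`` as degrees and weights cell
areas by the cosine of latitude; it exists for realism but planar is the
testing default because it removes projection complications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: km per degree of latitude (spherical Earth, mean radius)
KM_PER_DEGREE = 111.195


@dataclass(frozen=True)
class GridSpec:
    """Shape and geometry of a raster grid.  Row 0 is the top (north) edge."""

    n_rows: int
    n_cols: int
    cell_size: float = 50.0
    mode: str = "planar"
    lat_top: float = 60.0  # geographic mode: latitude of the top row centre

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.mode not in ("planar", "geographic"):
            raise ValueError(f"unknown grid mode {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def latitudes(self) -> np.ndarray:
        """Latitude of each row centre (geographic mode)."""
        return self.lat_top - np.arange(self.n_rows) * self.cell_size

    def cell_areas(self) -> np.ndarray:
        """Cell areas in km^2, shape (n_rows, n_cols)."""
        if self.mode == "planar":
            return np.full(self.shape, self.cell_size**2)
        lat = np.deg2rad(self.latitudes())
        row_area = (KM_PER_DEGREE * self.cell_size) ** 2 * np.cos(lat)
        return np.repeat(row_area[:, None], self.n_cols, axis=1)

    def cell_size_km(self) -> float:
        """Centre-to-centre spacing in km along a row/column (planar mode)."""
        if self.mode == "planar":
            return self.cell_size
        # geographic: use the latitude-mean spacing as a scalar approximation
        lat = np.deg2rad(self.latitudes())
        return float(KM_PER_DEGREE * self.cell_size * np.mean(np.cos(lat)))
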