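"""Regular latitude-longitude grid with a flat cell indexing.

Cells are indexed row-major: ``cell = row * n_lon + col``.  Cell centers follow
the convention ``lat = -90 + res/2 + row * res`` and
``lon = -180 + res/2 + col * res``; row 0 is the southernmost row and
longitudes wrap at the antimeridian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat-lon grid.

    Parameters
    ----------
    n_lat, n_lon
        Number of grid rows (latitude) and columns (longitude).
    resolution_deg
        Cell edge length in degrees; the grid must fit on the sphere
        (``n_lat * resolution_deg <= 180``, ``n_lon * resolution_deg <= 360``).
    """

    n_lat: int
    n_lon: int
    resolution_deg: float

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ParameterError("grid must have at least one row and one column")
        if self.resolution_deg <= 0:
            raise ParameterError("resolution_deg must be positive")
        if self.n_lat * self.resolution_deg > 180 + 1e-9:
            raise ParameterError("n_lat * resolution_deg exceeds 180 degrees")
        if self.n_lon * self.resolution_deg > 360 + 1e-9:
            raise ParameterError("n_lon * resolution_deg exceeds 360 degrees")

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    # -- index conversions ---------------------------------------------------

    def cell_index(self, row, col):
        """Flat cell index of (row, col); accepts scalars or arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        if np.any((row < 0) | (row >= self.n_lat)) or np.any(
            (col < 0) | (col >= self.n_lon)
        ):
            raise ValidationError("row/col outside grid")
        out = row * self.n_lon + col
        return out if out.ndim else int(out)

    def rowcol(self, cell):
        """(row, col) of a flat cell index; accepts scalars or arrays."""
        cell = np.asarray(cell)
        if np.any((cell < 0) | (cell >= self.n_cells)):
            raise ValidationError("cell index outside grid")
        row, col = np.divmod(cell, self.n_lon)
        if cell.ndim:
            return row, col
        return int(row), int(col)

    def latlon(self, cell):
        """Cell-center latitude and longitude (degrees) of a flat index."""
        row, col = self.rowcol(cell)
        lat = -90.0 + self.resolution_deg / 2.0 + np.asarray(row) * self.resolution_deg
        lon = -180.0 + self.resolution_deg / 2.0 + np.asarray(col) * self.resolution_deg
        if np.asarray(cell).ndim:
            return lat, lon
        return float(lat), float(lon)

    def cell_latitudes(self) -> np.ndarray:
        """Latitude of every cell center, aligned with flat indexing."""
        rows = np.arange(self.n_cells) // self.n_lon
        return -90.0 + self.resolution_deg / 2.0 + rows * self.resolution_deg

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_lat": self.n_lat,
            "n_lon": self.n_lon,
            "resolution_deg": self.resolution_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        try:
            return cls(int(d["n_lat"]), int(d["n_lon"]), float(d["resolution_deg"]))
        except KeyError as exc:  # pragma: no cover - trivial
            raise ValidationError(f"grid spec missing field {exc}") from exc
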