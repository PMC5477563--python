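"""Regular latitude/longitude grid geometry.

All grids in this package are plain (unprojected) geographic grids: rows run
north to south, columns west to east, with constant angular cell sizes.  A
grid is described by its north-west origin, the cell steps, the number of
rows/columns, and whether the origin refers to the outer *edge* of the first
cell or its *center*.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GridSpec"]

#: slack allowed when checking that a grid does not overshoot the globe
_EXTENT_TOL = 1e-6


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular geographic grid.

    Parameters
    ----------
    n_rows, n_cols:
        Grid shape; rows are ordered north to south.
    lat_step, lon_step:
        Cell size in degrees (both positive).
    lat_origin:
        Latitude of the grid's northern limit. With ``registration="edge"``
        this is the outer edge of the first row; with ``"center"`` it is the
        first row's cell center.
    lon_origin:
        Longitude of the western limit, interpreted the same way.
    registration:
        ``"edge"`` (default) or ``"center"``.
    """

    n_rows: int
    n_cols: int
    lat_step: float
    lon_step: float
    lat_origin: float = 90.0
    lon_origin: float = -180.0
    registration: str = "edge"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.lat_step <= 0 or self.lon_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.registration not in ("edge", "center"):
            raise ValueError(f"unknown registration {self.registration!r}")
        if self.n_rows * self.lat_step > 180.0 + _EXTENT_TOL:
            raise ValueError("grid spans more than 180 degrees of latitude")
        if self.n_cols * self.lon_step > 360.0 + _EXTENT_TOL:
            raise ValueError("grid spans more than 360 degrees of longitude")

    # ------------------------------------------------------------------ edges
    @property
    def north_edge(self) -> float:
        if self.registration == "edge":
            return self.lat_origin
        return self.lat_origin + self.lat_step / 2.0

    @property
    def west_edge(self) -> float:
        if self.registration == "edge":
            return self.lon_origin
        return self.lon_origin - self.lon_step / 2.0

    @property
    def south_edge(self) -> float:
        return self.north_edge - self.n_rows * self.lat_step

    @property
    def east_edge(self) -> float:
        return self.west_edge + self.n_cols * self.lon_step

    # ---------------------------------------------------------------- centers
    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, one per row, descending (north first)."""
        return self.north_edge - (np.arange(self.n_rows) + 0.5) * self.lat_step

    @property
    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, one per column, ascending."""
        return self.west_edge + (np.arange(self.n_cols) + 0.5) * self.lon_step

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast (lat, lon) center arrays of shape ``(n_rows, n_cols)``."""
        lat = np.repeat(self.lat_centers[:, None], self.n_cols, axis=1)
        lon = np.repeat(self.lon_centers[None, :], self.n_rows, axis=0)
        return lat, lon

    def cell_area_weights(self) -> np.ndarray:
        """Relative spherical cell areas, shape ``(n_rows, n_cols)``.

        Proportional to cos(latitude) of the cell center; adequate for the
        latitude-weighted area fractions used in raster comparison.
        """
        w = np.cos(np.deg2rad(self.lat_centers)).clip(min=0.0)
        return np.repeat(w[:, None], self.n_cols, axis=1)

    # ------------------------------------------------------------------ misc
    def transform(self) -> tuple[float, float, float, float, float, float]:
        """GDAL-style affine transform ``(x0, dx, 0, y0, 0, -dy)``."""
        return (self.west_edge, self.lon_step, 0.0, self.north_edge, 0.0, -self.lat_step)

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/column of the cell center nearest to (lat, lon).

        Ties on a cell edge resolve to the lowest row index, then the lowest
        column index (argmin takes the first minimum; rows are scanned north
        to south, columns west to east).
        """
        row = int(np.argmin(np.abs(self.lat_centers - lat)))
        col = int(np.argmin(np.abs(self.lon_centers - lon)))
        return row, col

    def contains(self, lat: float, lon: float) -> bool:
        return (self.south_edge <= lat <= self.north_edge) and (
            self.west_edge <= lon <= self.east_edge
        )

    def as_center_registered(self) -> "GridSpec":
        if self.registration == "center":
            return self
        return replace(
            self,
            lat_origin=self.north_edge - self.lat_step / 2.0,
            lon_origin=self.west_edge + self.lon_step / 2.0,
            registration="center",
        )

    # ------------------------------------------------------------- factories
    @classmethod
    def global_native(cls) -> "GridSpec":
        """The native reanalysis grid: 540 columns x 360 rows.

        Cells are 2/3 degree of longitude by 1/2 degree of latitude, i.e.
        1/3 square degree each.
        """
        return cls(
            n_rows=360,
            n_cols=540,
            lat_step=0.5,
            lon_step=2.0 / 3.0,
            lat_origin=90.0,
            lon_origin=-180.0,
        )

    @classmethod
    def global_grid(cls, lat_step: float, lon_step: float) -> "GridSpec":
        n_rows = round(180.0 / lat_step)
        n_cols = round(360.0 / lon_step)
        return cls(n_rows=n_rows, n_cols=n_cols, lat_step=lat_step, lon_step=lon_step)
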