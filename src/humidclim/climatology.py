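"""Monthly climatology container: the input of the bioclim computation.

Per grid cell and calendar month, five numbers: the monthly minimum and
maximum of hourly temperature (degrees C) and the minimum / mean / maximum of
hourly specific humidity (kg/kg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec

__all__ = ["MonthlyClimatology"]

_FIELDS = ("tmin", "tmax", "hmin", "hmean", "hmax")


@dataclass
class MonthlyClimatology:
    """Twelve monthly records of temperature extremes and humidity summaries.

    All field arrays have shape ``(12, n_rows, n_cols)``, month axis first
    (January = index 0). Temperatures are degrees Celsius, humidity kg/kg.
    Missing cells are NaN (all five fields together).
    """

    grid: GridSpec
    year: int
    tmin: np.ndarray
    tmax: np.ndarray
    hmin: np.ndarray = field(repr=False)
    hmean: np.ndarray = field(repr=False)
    hmax: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = (12, self.grid.n_rows, self.grid.n_cols)
        for name in _FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != expected:
                raise ValueError(f"{name} has shape {arr.shape}, expected {expected}")
            setattr(self, name, arr)
        with np.errstate(invalid="ignore"):
            if np.any(self.tmin > self.tmax):
                raise ValueError("tmin must not exceed tmax in any month")
            if np.any(self.hmin > self.hmean) or np.any(self.hmean > self.hmax):
                raise ValueError("humidity must satisfy hmin <= hmean <= hmax")
            if np.nanmin(self.hmin, initial=0.0) < 0:
                raise ValueError("humidity must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def moisture(self, version_tag: str) -> np.ndarray:
        """The monthly moisture series for a humidity version tag."""
        try:
            return {"min": self.hmin, "mean": self.hmean, "max": self.hmax}[version_tag]
        except KeyError:
            raise ValueError(f"unknown humidity version {version_tag!r}") from None

    def cell(self, row: int, col: int) -> "MonthlyClimatology":
        """Single-cell view (1x1 grid) — convenient for per-cell oracles."""
        g = GridSpec(
            n_rows=1,
            n_cols=1,
            lat_step=self.grid.lat_step,
            lon_step=self.grid.lon_step,
            lat_origin=float(self.grid.lat_centers[row]),
            lon_origin=float(self.grid.lon_centers[col]),
            registration="center",
        )
        return MonthlyClimatology(
            grid=g,
            year=self.year,
            **{name: getattr(self, name)[:, row : row + 1, col : col + 1] for name in _FIELDS},
        )

    @classmethod
    def from_table(
        cls, table: np.ndarray, year: int = 0, grid: GridSpec | None = None
    ) -> "MonthlyClimatology":
        """Build a single-cell climatology from a 12x5 table.

        Columns: tmin, tmax, hmin, hmean, hmax.
        """
        table = np.asarray(table, dtype=float)
        if table.shape != (12, 5):
            raise ValueError(f"expected a 12x5 table, got shape {table.shape}")
        if grid is None:
            grid = GridSpec(n_rows=1, n_cols=1, lat_step=1.0, lon_step=1.0,
                            lat_origin=0.5, lon_origin=-0.5, registration="center")
        cols = {name: table[:, i].reshape(12, 1, 1) for i, name in enumerate(_FIELDS)}
        return cls(grid=grid, year=year, **cols)
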