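"""In-memory container for hourly gridded temperature / specific humidity.

The cube is the common currency between the synthetic generator, the NetCDF
reader and the monthly-climatology builder: a regular lat/lon grid, a strictly
increasing UTC time axis, 2 m air temperature in Kelvin and 2 m specific
humidity in kg water / kg air.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec

__all__ = ["HourlyCube", "DEFAULT_TEMP_VAR", "DEFAULT_HUM_VAR"]

DEFAULT_TEMP_VAR = "T2M"
DEFAULT_HUM_VAR = "QV2M"


@dataclass
class HourlyCube:
    """Hourly temperature and humidity fields on a regular grid.

    Attributes
    ----------
    grid:
        Grid geometry; rows north to south.
    times:
        Strictly increasing UTC timestamps, one per time slice.
    temperature:
        Kelvin, shape ``(n_times, n_rows, n_cols)``.
    humidity:
        kg water / kg air, same shape.
    """

    grid: GridSpec
    times: pd.DatetimeIndex
    temperature: np.ndarray
    humidity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        expected = (len(self.times), self.grid.n_rows, self.grid.n_cols)
        if self.temperature.shape != expected or self.humidity.shape != expected:
            raise ValueError(
                f"field shape mismatch: expected {expected}, got "
                f"T{self.temperature.shape} / Q{self.humidity.shape}"
            )
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if len(self.times) != len(self.times.unique()):
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        if np.nanmin(self.temperature) <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if np.nanmin(self.humidity) < 0:
            raise ValueError("specific humidity must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def cell_series(self, row: int, col: int) -> pd.DataFrame:
        """Hourly series for one cell as a DataFrame (temperature_K, humidity)."""
        return pd.DataFrame(
            {
                "temperature_K": self.temperature[:, row, col],
                "humidity": self.humidity[:, row, col],
            },
            index=self.times,
        )

    def to_dataset(self, temp_var: str = DEFAULT_TEMP_VAR, hum_var: str = DEFAULT_HUM_VAR) -> xr.Dataset:
        """Represent the cube as a CF-style xarray Dataset (time/lat/lon)."""
        return xr.Dataset(
            {
                temp_var: (
                    ("time", "lat", "lon"),
                    self.temperature,
                    {"units": "K", "long_name": "2-metre air temperature"},
                ),
                hum_var: (
                    ("time", "lat", "lon"),
                    self.humidity,
                    {"units": "kg kg-1", "long_name": "2-metre specific humidity"},
                ),
            },
            coords={
                "time": self.times,
                "lat": ("lat", self.grid.lat_centers, {"units": "degrees_north"}),
                "lon": ("lon", self.grid.lon_centers, {"units": "degrees_east"}),
            },
        )

    def to_netcdf(self, path, temp_var: str = DEFAULT_TEMP_VAR, hum_var: str = DEFAULT_HUM_VAR) -> None:
        """Write the cube as NetCDF3 (classic 64-bit offset) via scipy."""
        ds = self.to_dataset(temp_var=temp_var, hum_var=hum_var)
        ds.to_netcdf(str(path), engine="scipy", format="NETCDF3_64BIT")

    @classmethod
    def from_dataset(
        cls,
        ds: xr.Dataset,
        temp_var: str = DEFAULT_TEMP_VAR,
        hum_var: str = DEFAULT_HUM_VAR,
    ) -> "HourlyCube":
        """Build a cube from a CF-style dataset, normalising to north-up rows.

        South-up latitude axes are flipped so that row 0 is the northernmost
        cell; the values keep their (lat, lon) association.
        """
        for var in (temp_var, hum_var):
            if var not in ds:
                raise KeyError(f"variable {var!r} not found in dataset")
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        temperature = np.asarray(ds[temp_var].transpose("time", "lat", "lon").values, dtype=float)
        humidity = np.asarray(ds[hum_var].transpose("time", "lat", "lon").values, dtype=float)
        if len(lat) > 1 and lat[1] > lat[0]:  # south-up on disk
            lat = lat[::-1]
            temperature = temperature[:, ::-1, :]
            humidity = humidity[:, ::-1, :]
        lat_step = float(abs(lat[0] - lat[1])) if len(lat) > 1 else 1.0
        lon_step = float(abs(lon[1] - lon[0])) if len(lon) > 1 else 1.0
        grid = GridSpec(
            n_rows=len(lat),
            n_cols=len(lon),
            lat_step=lat_step,
            lon_step=lon_step,
            lat_origin=float(lat[0]),
            lon_origin=float(lon[0]),
            registration="center",
        )
        times = pd.DatetimeIndex(ds["time"].values)
        return cls(grid=grid, times=times, temperature=temperature, humidity=humidity)
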