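"""Synthetic hourly climate cubes, climatologies and station series.

Every downstream stage (ingest, bioclim computation, downscaling, validation
statistics) is exercised against data generated here with known structure:
a latitudinal temperature gradient, an annual cycle that flips phase across
hemispheres, a diurnal cycle, i.i.d. Gaussian noise, and specific humidity
coupled exponentially to temperature (a crude Clausius-Clapeyron analogue).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime

import numpy as np
import pandas as pd

from .climatology import MonthlyClimatology
from .cube import HourlyCube
from .grids import GridSpec
from .stations import StationSeries

__all__ = [
    "SynthParams",
    "gen_climate_cube",
    "gen_station_series",
    "gen_monthly_climatology",
    "TOY_SEASONAL_TABLE",
]

#: humidity is clipped to this physical range (kg/kg)
HUMIDITY_FLOOR = 1e-6
HUMIDITY_CEIL = 0.04

#: annual-cycle peak (day of year, mid-January in the northern hemisphere)
DAY_OF_PEAK = 15.0
#: diurnal-cycle peak hour (UTC; no local-solar offset is applied)
HOUR_OF_PEAK = 14.0
TROPICAL_YEAR_DAYS = 365.25


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic climate model.

    Defaults describe a mildly Earth-like planet: 26 degC at the equator
    falling by 0.6 degC per degree of latitude, a 10 degC seasonal swing,
    a 6 degC diurnal swing, 1 degC of hourly noise, and humidity of
    ~7.7 g/kg at 0 degC growing 6%/degC.
    """

    mean_temp_equator: float = 26.0  # degC
    lapse_per_deg_lat: float = 0.6  # degC per degree latitude
    seasonal_amplitude: float = 10.0  # degC
    diurnal_amplitude: float = 6.0  # degC
    noise_sd: float = 1.0  # degC
    humidity_ref: float = 0.0077  # kg/kg at 0 degC
    humidity_temp_coeff: float = 0.06  # 1/degC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seasonal_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 < self.humidity_ref <= HUMIDITY_CEIL):
            raise ValueError(f"humidity_ref must lie in (0, {HUMIDITY_CEIL}]")


def _deterministic_temperature(
    lat: np.ndarray, day_of_year: np.ndarray, hour: np.ndarray, params: SynthParams
) -> np.ndarray:
    """Noise-free temperature (degC); lat broadcast against time arrays."""
    # the annual peak is mid-January: summer in the southern hemisphere
    hemi = np.where(lat >= 0, -1.0, 1.0)
    seasonal = params.seasonal_amplitude * hemi * np.cos(
        2.0 * np.pi * (day_of_year - DAY_OF_PEAK) / TROPICAL_YEAR_DAYS
    )
    diurnal = params.diurnal_amplitude * np.cos(2.0 * np.pi * (hour - HOUR_OF_PEAK) / 24.0)
    return params.mean_temp_equator - params.lapse_per_deg_lat * np.abs(lat) + seasonal + diurnal


def humidity_from_temperature(temp_c: np.ndarray, params: SynthParams) -> np.ndarray:
    """Specific humidity coupled to temperature, clipped to physical range."""
    q = params.humidity_ref * np.exp(params.humidity_temp_coeff * temp_c)
    return np.clip(q, HUMIDITY_FLOOR, HUMIDITY_CEIL)


def gen_climate_cube(
    grid: GridSpec, start: date, end: date, params: SynthParams
) -> HourlyCube:
    """Generate an hourly cube covering ``[start, end)`` (end exclusive).

    The temperature model at a cell of latitude phi, day-of-year d, hour h:

        T(degC) = T_eq - lapse*|phi|
                  + A_seas * s(phi) * cos(2*pi*(d - d_peak)/365.25)
                  + A_diur * cos(2*pi*(h - 14)/24)
                  + N(0, noise_sd)

    with s(phi) = -1 north of the equator and +1 south of it, and d_peak in
    mid-January: the mid-January peak is southern summer, and northern
    summer aligns with southern winter.
    Humidity is q_ref*exp(c*T) clipped to [1e-6, 0.04] kg/kg. Output is in
    Kelvin and bit-reproducible for a fixed seed.
    """
    if start >= end:
        raise ValueError(f"end ({end}) must be after start ({start})")
    times = pd.date_range(
        datetime(start.year, start.month, start.day),
        datetime(end.year, end.month, end.day),
        freq="h",
        inclusive="left",
    )
    lat = grid.lat_centers[None, :, None]  # (1, n_rows, 1)
    doy = times.dayofyear.to_numpy(dtype=float)[:, None, None]
    hour = times.hour.to_numpy(dtype=float)[:, None, None]
    temp_c = np.broadcast_to(
        _deterministic_temperature(lat, doy, hour, params),
        (len(times), grid.n_rows, grid.n_cols),
    ).copy()
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        temp_c += rng.standard_normal(temp_c.shape) * params.noise_sd
    humidity = humidity_from_temperature(temp_c, params)
    return HourlyCube(grid=grid, times=times, temperature=temp_c + 273.15, humidity=humidity)


def gen_station_series(
    truth: pd.Series,
    slope: float,
    intercept: float,
    noise_sd: float,
    step_hours: int = 1,
    seed: int = 0,
    station_id: str = "SYN1",
    lat: float = 0.0,
    lon: float = 0.0,
) -> StationSeries:
    """Emulate a station whose records relate linearly to a gridded truth.

    The station value at each sampled instant is ``(truth - intercept)/slope
    + noise`` so that an ordinary least squares fit of the gridded series on
    the station series recovers (slope, intercept) — up to the attenuation
    induced by the station-side noise, which is negligible when the signal
    variance dominates ``noise_sd**2``.

    Parameters
    ----------
    truth:
        Timestamped temperature series (degC) of the collocated grid cell.
    step_hours:
        1 or 6; the truth series is subsampled to every ``step_hours`` hours.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if step_hours not in (1, 6):
        raise ValueError("step_hours must be 1 or 6")
    sub = truth.iloc[::step_hours]
    values = (sub.to_numpy(dtype=float) - intercept) / slope
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.standard_normal(len(values)) * noise_sd
    return StationSeries(
        station_id=station_id,
        lat=lat,
        lon=lon,
        times=pd.DatetimeIndex(sub.index),
        temperature=values,
        step_hours=step_hours,
    )


#: A mid-latitude seasonal single-cell climatology used as a shared fixture.
#: Columns: tmin (degC), tmax (degC), hmin, hmean, hmax (kg/kg), Jan..Dec.
TOY_SEASONAL_TABLE = np.array(
    [
        #  tmin   tmax    hmin     hmean    hmax
        [-8.0, 2.0, 0.0016, 0.0022, 0.0030],   # Jan
        [-6.5, 4.0, 0.0018, 0.0025, 0.0034],   # Feb
        [-2.0, 9.0, 0.0024, 0.0033, 0.0045],   # Mar
        [3.0, 15.0, 0.0034, 0.0047, 0.0063],   # Apr
        [8.0, 21.0, 0.0048, 0.0066, 0.0088],   # May
        [13.0, 26.0, 0.0065, 0.0089, 0.0117],  # Jun
        [15.0, 29.0, 0.0074, 0.0101, 0.0132],  # Jul
        [14.0, 28.0, 0.0070, 0.0096, 0.0126],  # Aug
        [9.5, 23.0, 0.0054, 0.0074, 0.0098],   # Sep
        [4.0, 16.0, 0.0037, 0.0051, 0.0068],   # Oct
        [-1.0, 8.0, 0.0026, 0.0035, 0.0047],   # Nov
        [-6.0, 3.0, 0.0018, 0.0024, 0.0033],   # Dec
    ]
)


def gen_monthly_climatology(preset="toy-seasonal", **kwargs) -> MonthlyClimatology:
    """Single-cell monthly climatology from a preset name or explicit table.

    Presets
    -------
    ``"constant"``:
        All 12 months identical; keywords ``c`` (temperature, degC, default
        10) and ``h`` (humidity, kg/kg, default 0.005).
    ``"toy-seasonal"``:
        The tabulated mid-latitude cycle in :data:`TOY_SEASONAL_TABLE`.

    Alternatively pass a 12x5 array (tmin, tmax, hmin, hmean, hmax) directly;
    monthly orderings (tmin <= tmax, hmin <= hmean <= hmax) are enforced.
    """
    if isinstance(preset, str):
        if preset == "constant":
            c = float(kwargs.pop("c", 10.0))
            h = float(kwargs.pop("h", 0.005))
            table = np.tile([c, c, h, h, h], (12, 1))
        elif preset == "toy-seasonal":
            table = TOY_SEASONAL_TABLE
        else:
            raise ValueError(f"unknown climatology preset {preset!r}")
        if kwargs:
            raise TypeError(f"unexpected keywords for preset {preset!r}: {sorted(kwargs)}")
    else:
        table = np.asarray(preset, dtype=float)
    return MonthlyClimatology.from_table(table, year=kwargs.pop("year", 0))
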