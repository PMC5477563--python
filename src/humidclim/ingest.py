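"""Reduce hourly NetCDF cubes to monthly climatologies.

The pipeline's first real stage: read CF-style hourly files (variables
``T2M`` in Kelvin and ``QV2M`` in kg/kg by default), then for each calendar
month take the minimum and maximum of all hourly temperatures and the
minimum / arithmetic mean / maximum of all hourly humidities.

Monthly temperature extremes are the extremes of *all* hourly values in the
month — not means of daily extremes, which is a different (station-data)
convention. Temperatures are converted from Kelvin to Celsius here, so every
downstream computation works in degrees Celsius.
"""

from __future__ import annotations

import calendar

import numpy as np
import pandas as pd
import xarray as xr

from .climatology import MonthlyClimatology
from .cube import DEFAULT_HUM_VAR, DEFAULT_TEMP_VAR, HourlyCube

__all__ = [
    "read_hourly_netcdf",
    "monthly_extremes",
    "build_year_climatology",
    "IngestError",
    "MissingVariableError",
    "GridMismatchError",
    "TimeOrderError",
    "CoverageError",
    "KELVIN_OFFSET",
    "DEFAULT_MIN_COVERAGE",
]

KELVIN_OFFSET = 273.15

#: fraction of a month's hours that must be present before extremes are taken
DEFAULT_MIN_COVERAGE = 0.9


class IngestError(Exception):
    """Base class for ingest failures."""


class MissingVariableError(IngestError):
    pass


class GridMismatchError(IngestError):
    pass


class TimeOrderError(IngestError):
    pass


class CoverageError(IngestError):
    pass


def read_hourly_netcdf(
    paths,
    temp_var: str = DEFAULT_TEMP_VAR,
    hum_var: str = DEFAULT_HUM_VAR,
) -> HourlyCube:
    """Read one or more hourly NetCDF files into a single time-sorted cube.

    Files may cover disjoint periods in any order; their grids must agree.
    South-up files are normalised to the package's north-up row order.
    """
    if isinstance(paths, (str, bytes)) or not hasattr(paths, "__iter__"):
        paths = [paths]
    paths = [str(p) for p in paths]
    if not paths:
        raise IngestError("no input files given")

    cubes = []
    for p in paths:
        with xr.open_dataset(p, engine="scipy") as ds:
            for var in (temp_var, hum_var):
                if var not in ds:
                    raise MissingVariableError(f"{p}: variable {var!r} not present")
            cubes.append(HourlyCube.from_dataset(ds.load(), temp_var=temp_var, hum_var=hum_var))

    grid = cubes[0].grid
    for p, c in zip(paths[1:], cubes[1:]):
        if c.grid != grid:
            raise GridMismatchError(f"{p}: grid differs from first file's grid")

    times = np.concatenate([c.times.asi8 for c in cubes])
    order = np.argsort(times, kind="stable")
    times_sorted = times[order]
    if np.any(np.diff(times_sorted) <= 0):
        raise TimeOrderError("concatenated files contain duplicate or non-monotone timestamps")
    temperature = np.concatenate([c.temperature for c in cubes], axis=0)[order]
    humidity = np.concatenate([c.humidity for c in cubes], axis=0)[order]
    return HourlyCube(
        grid=grid,
        times=pd.DatetimeIndex(times_sorted.view("datetime64[ns]")),
        temperature=temperature,
        humidity=humidity,
    )


def monthly_extremes(
    cube: HourlyCube,
    year: int,
    month: int,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, np.ndarray]:
    """Per-cell monthly summary: tmin, tmax (degC), hmin, hmean, hmax (kg/kg).

    ``tmin``/``tmax`` are the minimum/maximum over every hourly temperature
    value in the calendar month (converted K -> degC); ``hmean`` is the plain
    arithmetic mean of hourly humidity. Raises :class:`CoverageError` when
    fewer than ``min_coverage`` of the month's hours are present.
    """
    sel = (cube.times.year == year) & (cube.times.month == month)
    n_have = int(sel.sum())
    n_hours = calendar.monthrange(year, month)[1] * 24
    fraction = n_have / n_hours
    if fraction < min_coverage:
        raise CoverageError(
            f"{year}-{month:02d}: only {fraction:.1%} of the month's hours present "
            f"({n_have}/{n_hours}), below min_coverage={min_coverage}"
        )
    t = cube.temperature[sel]
    q = cube.humidity[sel]
    hmin = q.min(axis=0)
    hmax = q.max(axis=0)
    # summation round-off can push the mean one ulp past the extremes
    hmean = np.clip(q.mean(axis=0), hmin, hmax)
    return {
        "tmin": t.min(axis=0) - KELVIN_OFFSET,
        "tmax": t.max(axis=0) - KELVIN_OFFSET,
        "hmin": hmin,
        "hmean": hmean,
        "hmax": hmax,
    }


def build_year_climatology(
    cube: HourlyCube,
    year: int,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> MonthlyClimatology:
    """Assemble the 12 monthly summaries of one year into a climatology."""
    shape = (12, cube.grid.n_rows, cube.grid.n_cols)
    fields = {name: np.empty(shape) for name in ("tmin", "tmax", "hmin", "hmean", "hmax")}
    for month in range(1, 13):
        rec = monthly_extremes(cube, year, month, min_coverage=min_coverage)
        for name, arr in rec.items():
            fields[name][month - 1] = arr
    return MonthlyClimatology(grid=cube.grid, year=year, **fields)
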