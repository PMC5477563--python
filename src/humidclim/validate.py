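"""Validation statistics: station collocation and buffer-zone raster comparison.

Two families of checks mirror how gridded climate products are judged
against independent data:

* **Station collocation** — pair a gridded hourly series (nearest cell
  center) with a weather station's records on their common timestamps, then
  summarise the relation with Pearson's r, an ordinary least squares fit of
  the *gridded* series on the *station* series, the explained variance, and
  the interquartile range of the residuals (the "bias" scalar), plus
  per-calendar-month residual five-number summaries.

* **Buffer-zone raster comparison** — around each station draw a square
  buffer of 1/3 square degree (the native cell area), union the buffers,
  regress one raster on another over the cells whose centers fall inside,
  and map residual outliers by the Tukey fence rule (outside
  Q1 - 1.5*IQR .. Q3 + 1.5*IQR, quartiles by linear interpolation).

The regression orientation (grid as response) is the package default and can
be flipped by swapping the arguments; with station-side noise OLS attenuates
the slope, so recovered slopes are reliable only when the signal variance
dominates the noise.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from . import bioclim
from .climatology import MonthlyClimatology
from .cube import HourlyCube
from .grids import GridSpec
from .stations import StationSeries

__all__ = [
    "ComparisonStats",
    "BufferSet",
    "collocate",
    "series_stats",
    "station_bioclim",
    "buffer_zones",
    "raster_compare",
    "iqr_outliers",
    "BUFFER_AREA_DEG2",
]

#: buffer area in square degrees — the native grid's cell area
BUFFER_AREA_DEG2 = 1.0 / 3.0

#: temperature-only bioclim variables computable from a station record
STATION_VARIABLES = bioclim.TEMPERATURE_VARIABLES


@dataclass
class ComparisonStats:
    """Summary of a paired comparison (gridded response vs predictor)."""

    n: int
    pearson_r: float
    slope: float
    intercept: float
    r_squared: float
    residual_q1: float
    residual_q3: float
    residual_iqr: float
    per_month: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("pearson_r outside [-1, 1]")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")
        if self.residual_iqr < -1e-12:
            raise ValueError("residual IQR must be non-negative")


def collocate(cube: HourlyCube, station: StationSeries) -> pd.DataFrame:
    """Pair the nearest grid cell's series with the station's records.

    Returns a DataFrame indexed by the common timestamps with columns
    ``grid`` (degC, converted from the cube's Kelvin) and ``station`` (degC).
    Six-hourly stations match only the exact shared hours. A station on a
    cell edge resolves to the lowest row index, then the lowest column.
    """
    if not cube.grid.contains(station.lat, station.lon):
        raise ValueError(
            f"station {station.station_id} at ({station.lat}, {station.lon}) "
            f"is outside the cube extent"
        )
    row, col = cube.grid.nearest_cell(station.lat, station.lon)
    grid_series = pd.Series(cube.temperature[:, row, col] - 273.15, index=cube.times)
    common = cube.times.intersection(station.times)
    if len(common) == 0:
        raise ValueError("no common timestamps between cube and station")
    stn = pd.Series(station.temperature, index=station.times)
    return pd.DataFrame({"grid": grid_series.loc[common], "station": stn.loc[common]})


def _five_number(values: np.ndarray) -> dict[str, float]:
    q = np.percentile(values, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def series_stats(pairs: pd.DataFrame) -> ComparisonStats:
    """Regression and residual summaries of collocated pairs.

    OLS fits the ``grid`` column on the ``station`` column; residuals are
    grid minus fitted. Quartiles use linear interpolation between order
    statistics. If the index is a DatetimeIndex, per-calendar-month residual
    five-number summaries are included.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = pairs["station"].to_numpy(dtype=float)
    y = pairs["grid"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("station (predictor) series has zero variance")
    fit = sps.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    q1, q3 = np.percentile(residuals, [25, 75])
    per_month: dict[int, dict[str, float]] = {}
    if isinstance(pairs.index, pd.DatetimeIndex):
        months = pairs.index.month
        for m in range(1, 13):
            sel = months == m
            if sel.any():
                per_month[m] = _five_number(residuals[sel])
    return ComparisonStats(
        n=len(pairs),
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        residual_q1=float(q1),
        residual_q3=float(q3),
        residual_iqr=float(q3 - q1),
        per_month=per_month,
    )


def station_bioclim(
    station: StationSeries,
    years,
    min_coverage: float = 0.9,
) -> dict[str, float]:
    """Temperature-only bioclim values (BIO1-BIO7, BIO10, BIO11) from a station.

    Monthly tmin/tmax are the extremes of the station's observed values in
    each calendar month; each month must hold at least ``min_coverage`` of
    its expected records (month hours / step_hours). Multi-year ranges are
    averaged per variable, mirroring the decadal mean of gridded sets.
    """
    if isinstance(years, int):
        years = [years]
    years = list(years)
    temps = pd.Series(station.temperature, index=station.times)
    annual: list[dict[str, float]] = []
    failing: list[str] = []
    for year in years:
        tmin = np.empty((12, 1, 1))
        tmax = np.empty((12, 1, 1))
        for month in range(1, 13):
            sel = (temps.index.year == year) & (temps.index.month == month)
            expected = calendar.monthrange(year, month)[1] * 24 // station.step_hours
            if sel.sum() < min_coverage * expected:
                failing.append(f"{year}-{month:02d}")
                continue
            tmin[month - 1] = temps[sel].min()
            tmax[month - 1] = temps[sel].max()
        if failing:
            continue
        clim = MonthlyClimatology(
            grid=GridSpec(1, 1, 1.0, 1.0, station.lat + 0.5, station.lon - 0.5),
            year=year,
            tmin=tmin,
            tmax=tmax,
            hmin=np.full((12, 1, 1), 0.005),
            hmean=np.full((12, 1, 1), 0.005),
            hmax=np.full((12, 1, 1), 0.005),
        )
        bset = bioclim.annual_bioclim(clim, version="mean")
        annual.append({v: float(bset[v][0, 0]) for v in STATION_VARIABLES})
    if failing:
        raise ValueError(f"insufficient station coverage in: {', '.join(failing)}")
    return {v: float(np.mean([a[v] for a in annual])) for v in STATION_VARIABLES}


@dataclass
class BufferSet:
    """Square degree-space buffers of 1/3 deg^2 around stations, unioned."""

    stations: list[tuple[float, float]]
    polygons: list = field(repr=False)
    union: object = field(repr=False)

    @property
    def union_area(self) -> float:
        return float(self.union.area)


def buffer_zones(stations) -> BufferSet:
    """Build 1/3-square-degree square buffers centered on stations.

    The square side is sqrt(1/3) degrees (~0.577 deg). Buffers are clipped
    to the valid latitude band (a buffer at 82 degN cannot exceed the pole);
    overlapping buffers are unioned so shared area is not double-counted.
    """
    side = math.sqrt(BUFFER_AREA_DEG2)
    polys = []
    pts = []
    for lat, lon in stations:
        if not -90 <= lat <= 90:
            raise ValueError(f"invalid latitude {lat}")
        pts.append((float(lat), float(lon)))
        half = side / 2.0
        poly = shapely_box(lon - half, max(lat - half, -90.0), lon + half, min(lat + half, 90.0))
        polys.append(poly)
    union = unary_union(polys) if polys else shapely.geometry.Polygon()
    return BufferSet(stations=pts, polygons=polys, union=union)


def iqr_outliers(residuals: np.ndarray) -> np.ndarray:
    """Tukey-fence mask: outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    Quartiles use linear interpolation between order statistics. With an
    all-equal sample the fences collapse onto the common value and nothing
    is flagged.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 4:
        raise ValueError("need at least 4 residuals for the fence rule")
    q1, q3 = np.percentile(residuals, [25, 75])
    iqr = q3 - q1
    return (residuals < q1 - 1.5 * iqr) | (residuals > q3 + 1.5 * iqr)


def raster_compare(
    a: np.ndarray,
    b: np.ndarray,
    grid: GridSpec,
    buffers: BufferSet,
) -> tuple[ComparisonStats, np.ndarray, float]:
    """Compare raster ``a`` (response) against ``b`` (predictor) inside buffers.

    Both rasters must share ``grid`` (resample beforehand if not). The
    statistics use the cells whose centers fall in the buffer union; outliers
    are flagged on the OLS residuals by the Tukey fence rule. Returns
    ``(stats, outlier_mask, outlier_area_fraction)`` where the mask has the
    grid's shape and the fraction is the latitude-weighted area of outlier
    cells over all compared cells.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != grid.shape or b.shape != grid.shape:
        raise ValueError("rasters must be on the comparison grid")
    lat, lon = grid.cell_centers()
    inside = shapely.contains_xy(buffers.union, lon.ravel(), lat.ravel()).reshape(grid.shape)
    inside &= np.isfinite(a) & np.isfinite(b)
    if not inside.any():
        raise ValueError("no raster cells fall inside the buffer zones")
    pairs = pd.DataFrame({"grid": a[inside], "station": b[inside]})
    cstats = series_stats(pairs)
    residuals = a[inside] - (cstats.slope * b[inside] + cstats.intercept)
    flags = iqr_outliers(residuals)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[inside] = flags
    weights = grid.cell_area_weights()
    fraction = float(weights[mask].sum() / weights[inside].sum())
    return cstats, mask, fraction
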