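"""The 19 bioclimatic variables from monthly climate summaries.

Temperature variables (BIO1-BIO11) follow the classic definitions used in
ecological niche modelling; the moisture axis is monthly specific humidity
(kg/kg) instead of precipitation, in one of three versions: the monthly
minimum, mean or maximum humidity. "Quarters" are the 12 cyclically
consecutive three-month windows of the year ({Jan,Feb,Mar}, ..., {Dec,Jan,
Feb}); the wettest quarter is the window maximising the moisture sum, the
warmest the one maximising mean temperature, with ties broken by the
earliest start month. This is the rolling-window convention of the R
``dismo::biovars`` function, not calendar quarters.

Because the moisture series is a humidity (an intensive quantity), sums over
months are ecologically meaningless as-is; :func:`apply_ecological_rescale`
divides BIO12 by 12 and BIO16-BIO19 by 3 so that they report annual and
quarterly *mean* humidity.

Variable summary (pre-quantisation units):

=====  ==================================================  ==========
name   description                                         units
=====  ==================================================  ==========
BIO1   annual mean temperature                             degC
BIO2   mean diurnal range (monthly tmax - tmin, averaged)  degC
BIO3   isothermality, 100*BIO2/BIO7                        percent
BIO4   temperature seasonality (sd of monthly means x100)  degC x 100
BIO5   max temperature of warmest month                    degC
BIO6   min temperature of coldest month                    degC
BIO7   temperature annual range (BIO5 - BIO6)              degC
BIO8   mean temperature of most humid quarter              degC
BIO9   mean temperature of least humid quarter             degC
BIO10  mean temperature of warmest quarter                 degC
BIO11  mean temperature of coldest quarter                 degC
BIO12  annual humidity (sum; /12 -> annual mean)           kg/kg
BIO13  humidity of most humid month                        kg/kg
BIO14  humidity of least humid month                       kg/kg
BIO15  humidity seasonality (coefficient of variation)     percent
BIO16  humidity of most humid quarter (sum; /3 -> mean)    kg/kg
BIO17  humidity of least humid quarter (sum; /3 -> mean)   kg/kg
BIO18  humidity of warmest quarter (sum; /3 -> mean)       kg/kg
BIO19  humidity of coldest quarter (sum; /3 -> mean)       kg/kg
=====  ==================================================  ==========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .climatology import MonthlyClimatology
from .grids import GridSpec

__all__ = [
    "VERSIONS",
    "VARIABLE_NAMES",
    "TEMPERATURE_VARIABLES",
    "MOISTURE_VARIABLES",
    "VARIABLE_INFO",
    "BioclimSet",
    "cyclic_windows",
    "select_window",
    "annual_bioclim",
    "apply_ecological_rescale",
    "decadal_mean",
]

VERSIONS = ("min", "mean", "max")
VARIABLE_NAMES = tuple(f"BIO{i}" for i in range(1, 20))
#: variables independent of the humidity version
TEMPERATURE_VARIABLES = ("BIO1", "BIO2", "BIO3", "BIO4", "BIO5", "BIO6", "BIO7", "BIO10", "BIO11")
#: variables that depend (directly or through window selection) on moisture
MOISTURE_VARIABLES = tuple(v for v in VARIABLE_NAMES if v not in TEMPERATURE_VARIABLES)

_TEMP_SCALE = 10
_HUM_SCALE = 100_000

VARIABLE_INFO: dict[str, dict] = {
    "BIO1": {"description": "Annual Mean Temperature", "units": "degC", "scale_factor": _TEMP_SCALE},
    "BIO2": {"description": "Mean Diurnal Range Temperature", "units": "degC", "scale_factor": _TEMP_SCALE},
    "BIO3": {"description": "Isothermality (BIO2/BIO7) (*100)", "units": "percent", "scale_factor": _TEMP_SCALE},
    "BIO4": {"description": "Temperature Seasonality (standard deviation *100)", "units": "degC*100", "scale_factor": _TEMP_SCALE},
    "BIO5": {"description": "Max Temperature of Warmest Month", "units": "degC", "scale_factor": _TEMP_SCALE},
    "BIO6": {"description": "Min Temperature of Coldest Month", "units": "degC", "scale_factor": _TEMP_SCALE},
    "BIO7": {"description": "Temperature Annual Range (BIO5-BIO6)", "units": "degC", "scale_factor": _TEMP_SCALE},
    "BIO8": {"description": "Mean temperature of most humid quarter", "units": "degC", "scale_factor": _TEMP_SCALE},
    "BIO9": {"description": "Mean temperature of least humid quarter", "units": "degC", "scale_factor": _TEMP_SCALE},
    "BIO10": {"description": "Mean Temperature of Warmest Quarter", "units": "degC", "scale_factor": _TEMP_SCALE},
    "BIO11": {"description": "Mean Temperature of Coldest Quarter", "units": "degC", "scale_factor": _TEMP_SCALE},
    "BIO12": {"description": "Annual Mean Specific Humidity", "units": "kg/kg", "scale_factor": _HUM_SCALE},
    "BIO13": {"description": "Specific Humidity of most humid Month", "units": "kg/kg", "scale_factor": _HUM_SCALE},
    "BIO14": {"description": "Specific Humidity of least humid Month", "units": "kg/kg", "scale_factor": _HUM_SCALE},
    "BIO15": {"description": "Specific Humidity seasonality (Coefficient of variation)", "units": "percent", "scale_factor": _HUM_SCALE},
    "BIO16": {"description": "Specific Humidity Mean of most humid quarter", "units": "kg/kg", "scale_factor": _HUM_SCALE},
    "BIO17": {"description": "Specific Humidity Mean of least humid quarter", "units": "kg/kg", "scale_factor": _HUM_SCALE},
    "BIO18": {"description": "Specific Humidity Mean of warmest quarter", "units": "kg/kg", "scale_factor": _HUM_SCALE},
    "BIO19": {"description": "Specific Humidity Mean of coldest quarter", "units": "kg/kg", "scale_factor": _HUM_SCALE},
}


@dataclass
class BioclimSet:
    """One version's 19 bioclim layers for one period on one grid.

    ``rescaled`` records whether the ecological rescaling (BIO12/12,
    BIO16-19/3) has been applied; it guards against double application.
    """

    grid: GridSpec
    version: str
    period: str
    layers: dict[str, np.ndarray] = field(repr=False)
    rescaled: bool = False

    def __post_init__(self) -> None:
        if self.version not in VERSIONS:
            raise ValueError(f"version must be one of {VERSIONS}, got {self.version!r}")
        missing = [v for v in VARIABLE_NAMES if v not in self.layers]
        if missing:
            raise ValueError(f"incomplete bioclim set, missing: {missing}")
        for name in VARIABLE_NAMES:
            arr = np.asarray(self.layers[name])
            if arr.dtype.kind != "f":  # keep float32 layers as-is (memory)
                arr = arr.astype(float)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected grid shape {self.grid.shape}"
                )
            self.layers[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def metadata(self, name: str) -> dict:
        return VARIABLE_INFO[name]


def cyclic_windows(values: np.ndarray) -> np.ndarray:
    """Sums of the 12 cyclic three-month windows.

    ``values`` has the 12 months on axis 0 (any trailing cell axes). Window
    ``i`` (0-based start month) sums months ``i, i+1, i+2`` modulo 12; the
    window starting in December wraps to {Dec, Jan, Feb}.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != 12:
        raise ValueError(f"expected 12 months on axis 0, got {values.shape[0]}")
    rolled = np.concatenate([values, values[:2]], axis=0)
    return rolled[:12] + rolled[1:13] + rolled[2:14]


def select_window(window_values: np.ndarray, mode: str) -> np.ndarray:
    """Start month (1..12) of the extreme window; ties -> earliest start.

    ``mode`` is ``"max"`` or ``"min"``; month axis is axis 0.
    """
    window_values = np.asarray(window_values, dtype=float)
    if window_values.shape[0] != 12:
        raise ValueError(f"expected 12 windows on axis 0, got {window_values.shape[0]}")
    if mode == "max":
        idx = np.argmax(window_values, axis=0)
    elif mode == "min":
        idx = np.argmin(window_values, axis=0)
    else:
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    return idx + 1


def _take_window(window_stat: np.ndarray, start_month: np.ndarray) -> np.ndarray:
    """Value of ``window_stat`` (12, ...) at each cell's selected start month."""
    return np.take_along_axis(window_stat, (start_month - 1)[None, ...], axis=0)[0]


def annual_bioclim(
    clim: MonthlyClimatology,
    version: str = "mean",
    cv_offset: float = 0.0,
) -> BioclimSet:
    """Compute the 19 bioclim layers for one year and one humidity version.

    Notes
    -----
    * BIO4 uses the sample standard deviation (n-1) of the 12 monthly mean
      temperatures, times 100.
    * BIO15 is ``100*sd/mean`` of the monthly moisture plus ``cv_offset``.
      The default offset is 0; pass ``cv_offset=1.0`` to emulate the
      precipitation-oriented ``biovars`` behaviour literally — on kg/kg
      inputs that collapses the CV towards zero, hence it is not the default.
    * BIO3 is undefined (NaN) where the annual range BIO7 is zero; BIO15 is
      undefined where the offset moisture has zero mean.
    * The returned set is *pre*-rescale: BIO12 and BIO16-BIO19 are raw
      window/annual sums until :func:`apply_ecological_rescale`.
    * A NaN in any monthly input marks all 19 outputs NaN for that cell.
    """
    if version not in VERSIONS:
        raise ValueError(f"version must be one of {VERSIONS}, got {version!r}")
    tmin, tmax = clim.tmin, clim.tmax
    moisture = clim.moisture(version)
    bad = (
        np.isnan(tmin).any(axis=0)
        | np.isnan(tmax).any(axis=0)
        | np.isnan(moisture).any(axis=0)
    )

    tavg = (tmin + tmax) / 2.0
    out: dict[str, np.ndarray] = {}
    out["BIO1"] = tavg.mean(axis=0)
    out["BIO2"] = (tmax - tmin).mean(axis=0)
    out["BIO4"] = tavg.std(axis=0, ddof=1) * 100.0
    out["BIO5"] = tmax.max(axis=0)
    out["BIO6"] = tmin.min(axis=0)
    out["BIO7"] = out["BIO5"] - out["BIO6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["BIO3"] = np.where(out["BIO7"] != 0, 100.0 * out["BIO2"] / out["BIO7"], np.nan)

    tavg_window_mean = cyclic_windows(tavg) / 3.0
    moist_window_sum = cyclic_windows(moisture)
    # NaN-safe selection: argmax/argmin would propagate NaN inconsistently
    safe_moist = np.where(np.isnan(moist_window_sum), -np.inf, moist_window_sum)
    humid_start = select_window(safe_moist, "max")
    arid_start = select_window(np.where(np.isnan(moist_window_sum), np.inf, moist_window_sum), "min")
    warm_start = select_window(np.where(np.isnan(tavg_window_mean), -np.inf, tavg_window_mean), "max")
    cold_start = select_window(np.where(np.isnan(tavg_window_mean), np.inf, tavg_window_mean), "min")

    out["BIO8"] = _take_window(tavg_window_mean, humid_start)
    out["BIO9"] = _take_window(tavg_window_mean, arid_start)
    out["BIO10"] = _take_window(tavg_window_mean, warm_start)
    out["BIO11"] = _take_window(tavg_window_mean, cold_start)

    out["BIO12"] = moisture.sum(axis=0)
    out["BIO13"] = moisture.max(axis=0)
    out["BIO14"] = moisture.min(axis=0)
    shifted = moisture + cv_offset
    mean_shift = shifted.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["BIO15"] = np.where(
            mean_shift != 0, 100.0 * shifted.std(axis=0, ddof=1) / mean_shift, np.nan
        )
    out["BIO16"] = _take_window(moist_window_sum, humid_start)
    out["BIO17"] = _take_window(moist_window_sum, arid_start)
    out["BIO18"] = _take_window(moist_window_sum, warm_start)
    out["BIO19"] = _take_window(moist_window_sum, cold_start)

    if bad.any():
        for name in VARIABLE_NAMES:
            out[name] = np.where(bad, np.nan, out[name])
    return BioclimSet(
        grid=clim.grid, version=version, period=str(clim.year), layers=out, rescaled=False
    )


def apply_ecological_rescale(raw: BioclimSet) -> BioclimSet:
    """Turn moisture sums into means: BIO12/12 and BIO16-BIO19/3.

    With a humidity moisture axis the raw annual and quarterly *sums* have no
    ecological meaning; dividing by the number of summed months yields the
    annual mean humidity (BIO12) and quarterly mean humidities (BIO16-19).
    Applying the rescale twice is an error.
    """
    if raw.rescaled:
        raise ValueError("ecological rescale already applied to this set")
    layers = dict(raw.layers)
    layers["BIO12"] = layers["BIO12"] / 12.0
    for name in ("BIO16", "BIO17", "BIO18", "BIO19"):
        layers[name] = layers[name] / 3.0
    return replace(raw, layers=layers, rescaled=True)


def decadal_mean(annuals: list[BioclimSet], period: str = "decade") -> BioclimSet:
    """Per-variable, per-cell arithmetic mean of annual sets.

    All sets must share grid, version and rescale state; a NaN in any year
    propagates to the decadal cell.
    """
    if not annuals:
        raise ValueError("need at least one annual set")
    first = annuals[0]
    for s in annuals[1:]:
        if s.grid != first.grid:
            raise ValueError("annual sets are on different grids")
        if s.version != first.version:
            raise ValueError("annual sets mix humidity versions")
        if s.rescaled != first.rescaled:
            raise ValueError("annual sets mix rescaled and raw values")
    layers = {
        name: np.mean([s.layers[name] for s in annuals], axis=0) for name in VARIABLE_NAMES
    }
    return BioclimSet(
        grid=first.grid,
        version=first.version,
        period=period,
        layers=layers,
        rescaled=first.rescaled,
    )
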