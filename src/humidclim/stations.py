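"""Weather-station temperature series and their CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StationSeries", "read_station_csv", "write_station_csv"]


@dataclass
class StationSeries:
    """One station's timestamped 2 m temperatures.

    ``step_hours`` is the nominal sampling interval (1 for hourly records,
    6 for six-hourly); gaps are allowed, sub-step sampling is not.
    """

    station_id: str
    lat: float
    lon: float
    times: pd.DatetimeIndex
    temperature: np.ndarray = field(repr=False)
    step_hours: int = 1

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if len(self.times) != len(self.temperature):
            raise ValueError("times and temperature must have equal length")
        if len(self.times) > 1:
            deltas = np.diff(self.times.asi8)
            if np.any(deltas <= 0):
                raise ValueError("timestamps must be strictly increasing")
            step_ns = self.step_hours * 3_600_000_000_000
            if np.any(deltas % step_ns != 0):
                raise ValueError(
                    f"timestamp spacing inconsistent with step_hours={self.step_hours}"
                )
        if self.step_hours not in (1, 6):
            raise ValueError("step_hours must be 1 or 6")

    def __len__(self) -> int:
        return len(self.times)

    def as_series(self) -> pd.Series:
        return pd.Series(self.temperature, index=self.times, name="temperature_C")


def write_station_csv(station: StationSeries, path) -> None:
    """CSV with columns station_id, lat, lon, timestamp, temperature_C."""
    df = pd.DataFrame(
        {
            "station_id": station.station_id,
            "lat": station.lat,
            "lon": station.lon,
            "timestamp": station.times.strftime("%Y-%m-%dT%H:%M:%S"),
            "temperature_C": station.temperature,
        }
    )
    df.to_csv(path, index=False)


def read_station_csv(path, step_hours: int | None = None) -> StationSeries:
    """Read a station series written by :func:`write_station_csv`.

    If ``step_hours`` is not given it is inferred from the smallest timestamp
    gap (1 or 6 hours).
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"station_id", "lat", "lon", "timestamp", "temperature_C"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"station CSV missing columns: {sorted(missing)}")
    df = df.sort_values("timestamp")
    times = pd.DatetimeIndex(df["timestamp"])
    if step_hours is None:
        if len(times) > 1:
            gap_h = int(np.diff(times.asi8).min() // 3_600_000_000_000)
            step_hours = 6 if gap_h >= 6 else 1
        else:
            step_hours = 1
    return StationSeries(
        station_id=str(df["station_id"].iloc[0]),
        lat=float(df["lat"].iloc[0]),
        lon=float(df["lon"].iloc[0]),
        times=times,
        temperature=df["temperature_C"].to_numpy(),
        step_hours=step_hours,
    )
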