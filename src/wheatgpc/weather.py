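"""Daily station-weather container shared by the simulator and the phenology rules.

A season's weather is a contiguous run of daily records for one county:
mean/max/min air temperature (°C), relative humidity (%), precipitation (mm)
and sunlight hours (h). Thermal-time arithmetic indexes days by offset from
the first record, so all window operations are O(window length).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order of the weather CSV dialect
WEATHER_COLUMNS = ["county_id", "date", "tmean_c", "tmax_c", "tmin_c",
                   "rh_pct", "precip_mm", "sun_h"]


class WeatherError(ValueError):
    """Raised for malformed weather series or out-of-range windows."""


@dataclass(frozen=True)
class DailyWeather:
    """One county's contiguous daily weather records.

    Parameters
    ----------
    county_id
        Short county identifier.
    frame
        DataFrame with columns ``date`` (datetime-like, strictly increasing,
        one record per calendar day with no gaps), ``tmean_c``, ``tmax_c``,
        ``tmin_c``, ``rh_pct``, ``precip_mm``, ``sun_h``.
    """

    county_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = set(WEATHER_COLUMNS) - {"county_id"}
        missing = required - set(self.frame.columns)
        if missing:
            raise WeatherError(f"weather frame missing columns: {sorted(missing)}")
        if len(self.frame) == 0:
            raise WeatherError("empty weather series")
        dates = pd.to_datetime(self.frame["date"]).dt.normalize()
        deltas = dates.diff().dropna().dt.days
        if len(deltas) and not (deltas == 1).all():
            raise WeatherError(
                f"{self.county_id}: dates must be contiguous daily records")
        f = self.frame.copy()
        f["date"] = dates
        f.reset_index(drop=True, inplace=True)
        object.__setattr__(self, "frame", f)

    # -- indexing helpers ---------------------------------------------------

    @property
    def start(self) -> dt.date:
        return self.frame["date"].iloc[0].date()

    @property
    def end(self) -> dt.date:
        """Last covered date (inclusive)."""
        return self.frame["date"].iloc[-1].date()

    def __len__(self) -> int:
        return len(self.frame)

    def _pos(self, day: dt.date) -> int:
        return (day - self.start).days

    def index_range(self, start: dt.date, end: dt.date) -> tuple[int, int]:
        """Positional bounds of the half-open window [start, end).

        Raises :class:`WeatherError` when the window is empty or falls
        outside the covered span.
        """
        if start >= end:
            raise WeatherError(f"empty window: {start} >= {end}")
        i, j = self._pos(start), self._pos(end)
        if i < 0 or j > len(self):
            raise WeatherError(
                f"window [{start}, {end}) outside series "
                f"[{self.start}, {self.end}]")
        return i, j

    def values(self, column: str, start: dt.date, end: dt.date) -> np.ndarray:
        """Column values over the half-open window [start, end)."""
        i, j = self.index_range(start, end)
        return self.frame[column].to_numpy()[i:j]

    @property
    def tmean(self) -> np.ndarray:
        return self.frame["tmean_c"].to_numpy()


def write_weather_csv(series_list: list[DailyWeather], path) -> None:
    """Write one or more county series to a single CSV (ISO-8601 dates)."""
    frames = []
    for s in series_list:
        f = s.frame.copy()
        f.insert(0, "county_id", s.county_id)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out[WEATHER_COLUMNS].to_csv(path, index=False)


def read_weather_csv(path) -> dict[str, list[DailyWeather]]:
    """Read the weather CSV dialect back into per-county series.

    Within a county, contiguous runs of dates become separate
    :class:`DailyWeather` objects (one per simulated season).
    """
    df = pd.read_csv(path, parse_dates=["date"])
    out: dict[str, list[DailyWeather]] = {}
    for county, grp in df.groupby("county_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        breaks = grp["date"].diff().dt.days.fillna(1).ne(1).cumsum()
        out[str(county)] = [
            DailyWeather(str(county), run.drop(columns=["county_id"]))
            for _, run in grp.groupby(breaks)
        ]
    return out
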