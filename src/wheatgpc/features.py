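"""Agro-climate feature construction over phenological windows.

Daily weather is aggregated into 29 predictors per county-year:

* 2 geographic: latitude, longitude;
* 7 for the whole season (sowing→maturity): mean tmean/tmax/tmin, GDD,
  mean RH, total precipitation, total sunshine;
* 5 for each of the four reproductive-phase windows regreening→maturity,
  jointing→flowering, flowering→filling, filling→maturity: mean tmean,
  GDD, mean RH, total precipitation, total sunshine.

The dormancy window and the regreening→jointing window carry no
predictors. Temperature and relative humidity are averaged; GDD,
precipitation and sunshine are accumulated. Cultivar-level grain protein
content (GPC, %) is averaged to one response per county-year, since
replicate cultivars within a county-year share identical weather.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .phenology import PhenologyCalendar, compute_gdd
from .weather import DailyWeather

__all__ = ["WINDOWS", "FEATURE_COLUMNS", "FEATURE_SPEC", "QualityClass",
           "window_aggregate", "build_features", "average_gpc",
           "classify_quality"]

#: phenological windows (label, start stage, end stage), half-open in days
WINDOWS: list[tuple[str, str, str]] = [
    ("sowing_maturity", "sowing", "maturity"),
    ("regreening_maturity", "regreening", "maturity"),
    ("jointing_flowering", "jointing", "flowering"),
    ("flowering_filling", "flowering", "filling"),
    ("filling_maturity", "filling", "maturity"),
]

_FULL_SEASON_VARS = ["tmean", "tmax", "tmin", "gdd", "rh", "precip", "sun"]
_WINDOW_VARS = ["tmean", "gdd", "rh", "precip", "sun"]

#: per-variable (weather column, statistic)
_VAR_DEF: dict[str, tuple[str, str]] = {
    "tmean": ("tmean_c", "mean"),
    "tmax": ("tmax_c", "mean"),
    "tmin": ("tmin_c", "mean"),
    "rh": ("rh_pct", "mean"),
    "precip": ("precip_mm", "sum"),
    "sun": ("sun_h", "sum"),
    "gdd": ("tmean_c", "gdd"),
}


def _feature_columns() -> tuple[list[str], dict[str, dict[str, str]]]:
    cols = ["lat", "lon"]
    spec = {
        "lat": {"window": "site", "statistic": "identity", "source": "latitude"},
        "lon": {"window": "site", "statistic": "identity", "source": "longitude"},
    }
    for label, start, end in WINDOWS:
        variables = _FULL_SEASON_VARS if label == "sowing_maturity" else _WINDOW_VARS
        for var in variables:
            name = f"{var}_{label}"
            col, stat = _VAR_DEF[var]
            cols.append(name)
            spec[name] = {"window": f"{start}->{end}", "statistic": stat,
                          "source": col}
    return cols, spec


#: canonical predictor names, in order (exactly 29)
FEATURE_COLUMNS, FEATURE_SPEC = _feature_columns()
assert len(FEATURE_COLUMNS) == 29


class QualityClass(enum.IntEnum):
    """Wheat-quality class from GPC: high ≥ 14 %, medium in [13, 14), low < 13."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


def window_aggregate(series: DailyWeather, start: dt.date, end: dt.date,
                     statistic: str, field: str) -> float:
    """Mean or sum of one weather field over the half-open window [start, end)."""
    v = series.values(field, start, end)
    if statistic == "mean":
        return float(v.mean())
    if statistic == "sum":
        return float(v.sum())
    raise ValueError(f"unknown statistic {statistic!r}")


def build_features(series: DailyWeather, calendar: PhenologyCalendar,
                   site: Mapping[str, object]) -> dict[str, float]:
    """Aggregate one county-season into the 29-predictor record.

    ``site`` must provide ``latitude`` and ``longitude`` (and may carry
    ``county_id``). Returns a plain dict with ``county_id``, ``year`` and
    the 29 canonical predictors.
    """
    if calendar.county_id != series.county_id:
        raise ValueError(
            f"calendar county {calendar.county_id!r} does not match "
            f"series county {series.county_id!r}")
    rec: dict[str, float] = {
        "county_id": series.county_id,
        "year": calendar.maturity.year,  # harvest year
        "lat": float(site["latitude"]),
        "lon": float(site["longitude"]),
    }
    for label, start_name, end_name in WINDOWS:
        start, end = calendar.stage_window(start_name, end_name)
        variables = _FULL_SEASON_VARS if label == "sowing_maturity" else _WINDOW_VARS
        for var in variables:
            col, stat = _VAR_DEF[var]
            if stat == "gdd":
                rec[f"{var}_{label}"] = compute_gdd(series, start, end)
            else:
                rec[f"{var}_{label}"] = window_aggregate(series, start, end,
                                                         stat, col)
    return rec


def average_gpc(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse cultivar-level GPC to one mean per (county, year).

    Input columns: ``county_id``, ``year``, ``cultivar``, ``gpc_pct``.
    Idempotent on already-collapsed tables.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["county_id", "year", "gpc_pct"])
    out = (records.groupby(["county_id", "year"], as_index=False)["gpc_pct"]
           .mean())
    return out


def classify_quality(gpc: float) -> QualityClass:
    """Quality class from GPC (%): high ≥ 14, medium in [13, 14), low < 13."""
    if not math.isfinite(gpc):
        raise ValueError(f"non-finite GPC: {gpc}")
    if gpc >= 14.0:
        return QualityClass.HIGH
    if gpc >= 13.0:
        return QualityClass.MEDIUM
    return QualityClass.LOW


def feature_table(feature_records: list[dict[str, float]],
                  gpc: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble feature records (plus optional averaged GPC) into one table.

    Columns: county_id, year, the 29 predictors, and ``gpc_pct`` when a GPC
    table is given (cultivar-level tables are averaged first).
    """
    feats = pd.DataFrame(feature_records)
    ordered = ["county_id", "year"] + FEATURE_COLUMNS
    feats = feats[ordered]
    if gpc is not None:
        if "cultivar" in gpc.columns:
            gpc = average_gpc(gpc)
        feats = feats.merge(gpc[["county_id", "year", "gpc_pct"]],
                            on=["county_id", "year"], how="inner")
    return feats
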