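"""Seeded synthetic Hebei-like data: daily weather, sites, and cultivar GPC.

The generator emulates a temperate continental monsoon climate across a
36.2–40.0° N latitude band: daily mean temperature follows a seasonal
sinusoid (coldest in mid-January) with a cooler north, relative humidity
and sunshine are drawn independently per day, precipitation is a
Bernoulli wet-day process with exponential amounts, and the north is
sunnier — so latitude is deliberately confounded with accumulated
sunshine and thermal time, as in the real study region.

Grain protein content (GPC, %) is generated from a *known* function of
the derived features: a broken-stick latitude ramp with its break at
38.0° N plus threshold effects of whole-season sunshine (> 1500 h),
filling→maturity thermal time (≥ 515 GDD) and filling→maturity relative
humidity (≥ 59 %), plus Gaussian cultivar noise. Every downstream stage
can therefore be tested for recovery of this ground truth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import build_features
from .phenology import PhenologyParams, derive_calendar
from .weather import DailyWeather

__all__ = ["SiteSpec", "WeatherGenParams", "GPCGenParams",
           "generate_weather", "generate_gpc", "generate_dataset",
           "constant_weather"]

SIGNAL_FEATURES = ("lat", "sun_sowing_maturity", "gdd_filling_maturity",
                   "rh_filling_maturity")


@dataclass(frozen=True)
class SiteSpec:
    """One county's location."""

    county_id: str
    latitude: float   # degrees N, in [36.0, 40.5]
    longitude: float  # degrees E, in [113.0, 120.0]

    def __post_init__(self) -> None:
        if not 36.0 <= self.latitude <= 40.5:
            raise ValueError(f"latitude {self.latitude} outside [36.0, 40.5]")
        if not 113.0 <= self.longitude <= 120.0:
            raise ValueError(f"longitude {self.longitude} outside [113.0, 120.0]")


@dataclass(frozen=True)
class WeatherGenParams:
    """Weather-simulation configuration (long-run climate of the band).

    Defaults are calibrated so that window summaries derived downstream
    (e.g. mean filling→maturity temperature ≈ 24 °C, whole-season sunshine
    ≈ 1550 h straddling 1500 h) resemble the study region's climate.
    """

    annual_mean_temp: float = 13.0        # °C at 38° N
    seasonal_amplitude: float = 14.5      # °C, sinusoid half-range
    daily_temp_noise_sd: float = 2.5      # °C
    diurnal_half_range: float = 5.5       # °C, (tmax − tmin)/2
    rh_mean: float = 57.0                 # %
    rh_sd: float = 12.0                   # % daily
    wet_day_prob: float = 0.15
    wet_day_mean_precip: float = 4.0      # mm on wet days
    sunshine_mean: float = 5.65           # h/day at 38° N
    sunshine_sd: float = 2.0              # h/day
    latitude_temp_gradient: float = -0.8  # °C per degree latitude
    latitude_sun_gradient: float = 0.35   # h/day per degree latitude
    county_temp_offset_sd: float = 0.6    # °C, persistent per-county offset
    county_sun_offset_sd: float = 0.6     # h/day, persistent per-county offset

    def __post_init__(self) -> None:
        for name in ("daily_temp_noise_sd", "rh_sd", "sunshine_sd",
                     "county_temp_offset_sd", "county_sun_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise ValueError("wet_day_prob must be in [0, 1]")


@dataclass(frozen=True)
class GPCGenParams:
    """Ground-truth GPC response surface.

    The broken-stick latitude term has slope ``south_lat_slope`` below
    ``lat_break`` and ``north_lat_slope`` above it (both in % per degree,
    evaluated as slope·(lat − lat_break)); threshold effects add a fixed
    bonus when the corresponding derived feature crosses its threshold.
    Effect sizes are chosen so the total signal is comparable to the
    ~0.9 % GPC standard deviation observed in regional surveys.
    """

    baseline_gpc: float = 14.0     # %
    lat_break: float = 38.0        # degrees N
    south_lat_slope: float = -0.4  # % per degree, lat <= break
    north_lat_slope: float = 0.25  # % per degree, lat > break
    sun_threshold: float = 1500.0  # h, whole-season accumulated sunshine
    sun_effect: float = 0.5        # %
    gdd_threshold: float = 515.0   # GDD, filling->maturity
    gdd_effect: float = 0.4        # %
    rh_threshold: float = 59.0     # %, filling->maturity mean RH
    rh_effect: float = 0.3         # %
    noise_sd: float = 0.5          # % per cultivar record

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 8.0 <= self.baseline_gpc <= 18.0:
            raise ValueError("baseline_gpc outside the physiological 8-18 % band")


def _season_dates(season_start_year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{season_start_year}-09-01",
                         f"{season_start_year + 1}-07-31", freq="D")


def seasonal_tmean(dates: pd.DatetimeIndex, latitude: float,
                   params: WeatherGenParams) -> np.ndarray:
    """Deterministic daily-mean-temperature sinusoid, minimum mid-January."""
    ref = pd.to_datetime({"year": dates.year, "month": 1, "day": 15})
    phase = 2.0 * np.pi * (dates - pd.DatetimeIndex(ref)).days / 365.25
    level = (params.annual_mean_temp
             + params.latitude_temp_gradient * (latitude - 38.0))
    return level - params.seasonal_amplitude * np.cos(phase)


def generate_weather(site: SiteSpec, season_start_year: int,
                     params: WeatherGenParams = WeatherGenParams(),
                     seed: int = 0) -> DailyWeather:
    """Simulate one county-season of daily weather (1 Sep – 31 Jul).

    Deterministic for fixed arguments. Daily mean temperature is the
    latitude-shifted sinusoid plus iid Gaussian noise; tmax/tmin bracket
    it by the diurnal half-range; RH, precipitation and sunshine are drawn
    independently per day and clamped to physical ranges.
    """
    rng = np.random.default_rng(seed)
    dates = _season_dates(season_start_year)
    n = len(dates)
    tmean = seasonal_tmean(dates, site.latitude, params)
    tmean = tmean + rng.normal(0.0, params.daily_temp_noise_sd, n) \
        if params.daily_temp_noise_sd > 0 else tmean.copy()
    rh = np.clip(rng.normal(params.rh_mean, params.rh_sd, n), 0.0, 100.0)
    wet = rng.random(n) < params.wet_day_prob
    precip = np.where(wet, rng.exponential(params.wet_day_mean_precip, n), 0.0)
    sun_level = (params.sunshine_mean
                 + params.latitude_sun_gradient * (site.latitude - 38.0))
    sun = np.maximum(rng.normal(sun_level, params.sunshine_sd, n), 0.0)
    frame = pd.DataFrame({
        "date": dates,
        "tmean_c": tmean,
        "tmax_c": tmean + params.diurnal_half_range,
        "tmin_c": tmean - params.diurnal_half_range,
        "rh_pct": rh,
        "precip_mm": precip,
        "sun_h": sun,
    })
    return DailyWeather(site.county_id, frame)


def generate_gpc(features: dict[str, float],
                 params: GPCGenParams = GPCGenParams(),
                 seed: int = 0) -> float:
    """Draw one cultivar's GPC (%) from the ground-truth response surface."""
    missing = [k for k in SIGNAL_FEATURES if k not in features]
    if missing:
        raise KeyError(f"features record missing {missing}")
    lat = features["lat"]
    slope = (params.south_lat_slope if lat <= params.lat_break
             else params.north_lat_slope)
    gpc = params.baseline_gpc + slope * (lat - params.lat_break)
    if features["sun_sowing_maturity"] > params.sun_threshold:
        gpc += params.sun_effect
    if features["gdd_filling_maturity"] >= params.gdd_threshold:
        gpc += params.gdd_effect
    if features["rh_filling_maturity"] >= params.rh_threshold:
        gpc += params.rh_effect
    if params.noise_sd > 0:
        gpc += float(np.random.default_rng(seed).normal(0.0, params.noise_sd))
    return float(gpc)


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0]
               % (2 ** 31))


def generate_dataset(n_counties: int, years: list[int],
                     cultivars_per_county_year: int = 3, seed: int = 0,
                     weather_params: WeatherGenParams = WeatherGenParams(),
                     gpc_params: GPCGenParams = GPCGenParams(),
                     phen_params: PhenologyParams = PhenologyParams(),
                     ) -> tuple[pd.DataFrame, dict[str, dict[int, DailyWeather]],
                                pd.DataFrame]:
    """Simulate a full multi-county, multi-year study.

    Counties are placed evenly across 36.2–40.0° N; each county-season's
    weather is simulated, its phenology derived, its features built, and
    ``cultivars_per_county_year`` cultivar GPC records drawn (replicates
    share the county-year features and differ only in response noise).
    ``years`` are harvest years; each season starts 1 Sep of the previous
    year.

    Returns ``(site table, {county: {harvest year: weather}}, GPC table)``.
    """
    if n_counties < 1:
        raise ValueError("n_counties must be >= 1")
    if not years:
        raise ValueError("years must be non-empty")
    lats = np.linspace(36.2, 40.0, n_counties)
    site_rng = np.random.default_rng(_child_seed(seed, 0))
    sites = pd.DataFrame({
        "county_id": [f"c{i:03d}" for i in range(n_counties)],
        "latitude": lats,
        "longitude": site_rng.uniform(113.5, 119.5, n_counties),
    })
    # persistent county climate offsets (elevation/microclimate), so that
    # weather is correlated with — but not a pure function of — latitude
    temp_offsets = site_rng.normal(0.0, weather_params.county_temp_offset_sd,
                                   n_counties)
    sun_offsets = site_rng.normal(0.0, weather_params.county_sun_offset_sd,
                                  n_counties)
    weather: dict[str, dict[int, DailyWeather]] = {}
    gpc_rows = []
    for i, site_row in sites.iterrows():
        site = SiteSpec(site_row["county_id"], site_row["latitude"],
                        site_row["longitude"])
        county_params = replace(
            weather_params,
            annual_mean_temp=weather_params.annual_mean_temp + temp_offsets[i],
            sunshine_mean=weather_params.sunshine_mean + sun_offsets[i])
        weather[site.county_id] = {}
        for j, harvest_year in enumerate(sorted(years)):
            w = generate_weather(site, harvest_year - 1, county_params,
                                 seed=_child_seed(seed, 1, i, j))
            weather[site.county_id][harvest_year] = w
            calendar = derive_calendar(w, phen_params)
            feats = build_features(w, calendar,
                                   {"latitude": site.latitude,
                                    "longitude": site.longitude})
            for k in range(cultivars_per_county_year):
                gpc_rows.append({
                    "county_id": site.county_id,
                    "year": harvest_year,
                    "cultivar": f"cv{k:02d}",
                    "gpc_pct": generate_gpc(
                        feats, gpc_params,
                        seed=_child_seed(seed, 2, i, j, k)),
                })
    return sites, weather, pd.DataFrame(gpc_rows)


def constant_weather(county_id: str, start: dt.date, end: dt.date,
                     tmean: float | list[tuple[dt.date, float]] = 15.0,
                     rh: float = 55.0, precip: float = 0.0,
                     sun: float = 6.0,
                     diurnal_half_range: float = 5.0) -> DailyWeather:
    """Piecewise-constant synthetic series for worked examples and tests.

    ``tmean`` is either a single constant or a list of ``(from_date, value)``
    change points (the first must be on/before ``start``); all other fields
    are constant. ``end`` is inclusive.
    """
    dates = pd.date_range(start, end, freq="D")
    if isinstance(tmean, (int, float)):
        t = np.full(len(dates), float(tmean))
    else:
        t = np.empty(len(dates))
        points = sorted(tmean)
        if pd.Timestamp(points[0][0]) > dates[0]:
            raise ValueError("first tmean change point must be <= start")
        for from_date, value in points:
            t[dates >= pd.Timestamp(from_date)] = value
    frame = pd.DataFrame({
        "date": dates,
        "tmean_c": t,
        "tmax_c": t + diurnal_half_range,
        "tmin_c": t - diurnal_half_range,
        "rh_pct": float(rh),
        "precip_mm": float(precip),
        "sun_h": float(sun),
    })
    return DailyWeather(county_id, frame)
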