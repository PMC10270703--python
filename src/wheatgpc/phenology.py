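"""Thermal-time derivation of winter-wheat stage dates from daily weather.

The six stages — sowing, dormancy onset, regreening, jointing, flowering,
filling and maturity — are derived for one county-season from daily mean
temperature alone:

* Growing degree days (GDD, base 0 °C) accumulate daily mean temperature
  clamped at zero. All inter-stage windows use the half-open convention
  [start, end), which makes GDD exactly additive across consecutive stages.
* Regreening is predicted from the negative accumulated temperature X
  (sum of sub-zero daily means, 1 Oct–15 Feb) via the linear model
  Y = −0.0703·X + 20.339, where Y = 1 means 1 February.
* Jointing and grain-filling onset are the first dates at which 380 and
  1160 GDD accumulate from regreening; flowering is back-calculated as the
  latest date at least 300 GDD before filling.
* Maturity is reached when the growth-rate regression
  rate = 0.0014 + 0.0006·GDD(regreening→maturity) attains 1, i.e. at the
  first date with ≥ (1 − 0.0014)/0.0006 ≈ 1664.33 GDD since regreening.
* Sowing is chosen in a late-September–mid-October search window so that
  sowing→dormancy GDD falls in the agronomically suitable 570–770 band,
  as close as possible to a 670 GDD target.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .weather import DailyWeather, WeatherError

__all__ = [
    "PhenologyParams", "PhenologyCalendar", "PhenologyError",
    "compute_gdd", "negative_accumulated_temperature", "regreening_date",
    "forward_stage_date", "flowering_date", "dormancy_onset",
    "choose_sowing_date", "growth_rate", "maturity_gdd_threshold",
    "derive_calendar",
]


class PhenologyError(ValueError):
    """A stage date could not be derived from the supplied series."""


@dataclass(frozen=True)
class PhenologyParams:
    """Thermal-time coefficients and thresholds for stage derivation.

    Defaults are the published regression coefficients and thresholds for
    winter wheat in the North China Plain; all are exposed for sensitivity
    analysis.
    """

    gdd_base_temp: float = 0.0                      # °C
    sowing_search_start: tuple[int, int] = (9, 20)  # (month, day) 20 Sep
    sowing_search_end: tuple[int, int] = (10, 20)   # inclusive, 20 Oct
    sowing_gdd_range: tuple[float, float] = (570.0, 770.0)
    sowing_gdd_target: float = 670.0
    nat_start: tuple[int, int] = (10, 1)            # 1 Oct
    nat_end: tuple[int, int] = (2, 15)              # inclusive, 15 Feb
    regreening_intercept: float = 20.339            # day index, 1 = 1 Feb
    regreening_slope: float = -0.0703               # day per °C·day
    jointing_gdd: float = 380.0
    filling_gdd: float = 1160.0
    flowering_to_filling_gdd: float = 300.0
    maturity_rate_intercept: float = 0.0014
    maturity_rate_slope: float = 0.0006             # per GDD
    dormancy_run_length: int = 5                    # consecutive sub-zero days
    dormancy_fallback: tuple[int, int] = (12, 15)   # 15 Dec


@dataclass(frozen=True)
class PhenologyCalendar:
    """The six derived stage dates for one county-season."""

    county_id: str
    sowing: dt.date
    dormancy_onset: dt.date
    regreening: dt.date
    jointing: dt.date
    flowering: dt.date
    filling: dt.date
    maturity: dt.date
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        order = [self.sowing, self.dormancy_onset, self.regreening,
                 self.jointing, self.flowering, self.filling, self.maturity]
        names = ["sowing", "dormancy_onset", "regreening", "jointing",
                 "flowering", "filling", "maturity"]
        for (na, a), (nb, b) in zip(zip(names, order), zip(names[1:], order[1:])):
            if not a < b:
                raise PhenologyError(
                    f"{self.county_id}: stage order violated: "
                    f"{na}={a} !< {nb}={b}")
        if (self.regreening.month, self.regreening.day) < (2, 1):
            raise PhenologyError(
                f"{self.county_id}: regreening {self.regreening} before 1 Feb")

    def stage_window(self, start: str, end: str) -> tuple[dt.date, dt.date]:
        return getattr(self, start), getattr(self, end)


def compute_gdd(series: DailyWeather, start: dt.date, end: dt.date,
                base: float = 0.0) -> float:
    """Accumulated growing degree days over the half-open window [start, end).

    Each day contributes max(tmean − base, 0); sub-`base` days contribute
    zero, so the sum is non-negative and exactly additive over adjacent
    windows.
    """
    t = series.values("tmean_c", start, end)
    return float(np.maximum(t - base, 0.0).sum())


def negative_accumulated_temperature(series: DailyWeather, start: dt.date,
                                     end: dt.date) -> float:
    """Sum of strictly sub-zero daily mean temperatures over [start, end).

    A day at exactly 0 °C contributes nothing. The result is ≤ 0 and is the
    predictor X of the regreening regression.
    """
    t = series.values("tmean_c", start, end)
    return float(t[t < 0.0].sum())


def regreening_date(x_nat: float, params: PhenologyParams = PhenologyParams(),
                    february_year: int | None = None) -> dt.date:
    """Regreening date from the negative accumulated temperature X.

    Y = slope·X + intercept is rounded to the nearest whole day (halves up)
    and mapped onto the calendar with Y = 1 meaning 1 February of
    ``february_year``; large Y rolls into March (leap Februaries roll a day
    later).
    """
    if x_nat > 0:
        raise PhenologyError(f"negative accumulated temperature > 0: {x_nat}")
    if february_year is None:
        raise PhenologyError("february_year is required to place the date")
    y = params.regreening_slope * x_nat + params.regreening_intercept
    day_index = math.floor(y + 0.5)  # round half up
    return dt.date(february_year, 2, 1) + dt.timedelta(days=day_index - 1)


def forward_stage_date(series: DailyWeather, origin: dt.date,
                       gdd_threshold: float,
                       params: PhenologyParams = PhenologyParams()) -> dt.date:
    """Earliest date d with ``compute_gdd(origin, d) >= gdd_threshold``.

    Accumulation starts on ``origin`` (inclusive); the returned date is the
    day *after* the one whose contribution first reaches the threshold,
    consistent with the half-open window convention.
    """
    if gdd_threshold <= 0:
        raise PhenologyError(f"threshold must be positive: {gdd_threshold}")
    t = series.values("tmean_c", origin, dt.date.fromordinal(
        series.end.toordinal() + 1))
    cum = np.cumsum(np.maximum(t - params.gdd_base_temp, 0.0))
    idx = np.searchsorted(cum, gdd_threshold)
    if idx >= len(cum):
        raise PhenologyError(
            f"threshold {gdd_threshold} GDD not reached from {origin} "
            f"before series end {series.end}")
    return origin + dt.timedelta(days=int(idx) + 1)


def flowering_date(series: DailyWeather, filling: dt.date,
                   params: PhenologyParams = PhenologyParams()) -> dt.date:
    """Back-calculated flowering: latest d < filling with ≥ 300 GDD to filling.

    Moving flowering one day later would drop the flowering→filling
    accumulation below the threshold.
    """
    need = params.flowering_to_filling_gdd
    t = series.values("tmean_c", series.start, filling)
    clamped = np.maximum(t[::-1] - params.gdd_base_temp, 0.0)  # back from filling-1
    cum = np.cumsum(clamped)
    idx = np.searchsorted(cum, need)
    if idx >= len(cum):
        raise PhenologyError(
            f"{need} GDD not accumulable before filling {filling}")
    return filling - dt.timedelta(days=int(idx) + 1)


def dormancy_onset(series: DailyWeather,
                   params: PhenologyParams = PhenologyParams()) -> dt.date:
    """Operational dormancy onset.

    First date on/after 1 November that begins ``dormancy_run_length``
    consecutive days with tmean < 0 °C; if no such run exists the fallback
    (15 December by default) is returned. The downstream use (ending the
    sowing→dormancy accumulation) is insensitive to the exact day because
    near-dormancy days contribute almost no GDD.
    """
    year = series.start.year
    search_start = dt.date(year, 11, 1)
    fallback = dt.date(year, *params.dormancy_fallback)
    if series.end < fallback:
        raise PhenologyError(f"series ends {series.end}, before {fallback}")
    t = series.values("tmean_c", search_start,
                      dt.date.fromordinal(series.end.toordinal() + 1))
    below = t < 0.0
    run = params.dormancy_run_length
    for i in range(len(below) - run + 1):
        if below[i:i + run].all():
            return search_start + dt.timedelta(days=i)
    return fallback


def choose_sowing_date(series: DailyWeather, dormancy: dt.date,
                       params: PhenologyParams = PhenologyParams()
                       ) -> tuple[dt.date, list[str]]:
    """Ideal sowing date by the suitable pre-dormancy GDD rule.

    Among candidate dates in the search window whose sowing→dormancy GDD
    lies in the suitable band (570–770 by default), the one closest to the
    670 GDD target is chosen, later date winning ties. If no candidate's
    accumulation falls in the band, the candidate closest to the band is
    returned together with a warning.

    Returns ``(date, warnings)``.
    """
    year = series.start.year
    w_start = dt.date(year, *params.sowing_search_start)
    w_end = dt.date(year, *params.sowing_search_end)
    if w_start < series.start or w_end >= dormancy:
        raise PhenologyError(
            f"sowing search window [{w_start}, {w_end}] outside "
            f"series start {series.start} / dormancy {dormancy}")
    lo, hi = params.sowing_gdd_range
    target = params.sowing_gdd_target
    best: tuple[float, dt.date] | None = None          # in-band candidates
    best_out: tuple[float, dt.date] | None = None      # distance to band
    day = w_start
    while day <= w_end:
        gdd = compute_gdd(series, day, dormancy, params.gdd_base_temp)
        if lo <= gdd <= hi:
            dist = abs(gdd - target)
            if best is None or dist <= best[0]:        # ties -> later date
                best = (dist, day)
        else:
            dist = lo - gdd if gdd < lo else gdd - hi
            if best_out is None or dist <= best_out[0]:
                best_out = (dist, day)
        day += dt.timedelta(days=1)
    if best is not None:
        return best[1], []
    assert best_out is not None
    return best_out[1], [
        f"no sowing candidate reaches [{lo}, {hi}] GDD before dormancy "
        f"{dormancy}; nearest misses by {best_out[0]:.1f} GDD"]


def growth_rate(gdd_since_regreening: float,
                params: PhenologyParams = PhenologyParams()) -> float:
    """Maturity growth-rate regression: rate = a + b·GDD(regreening→now)."""
    return (params.maturity_rate_intercept
            + params.maturity_rate_slope * gdd_since_regreening)


def maturity_gdd_threshold(params: PhenologyParams = PhenologyParams()) -> float:
    """Cumulative GDD since regreening at which the growth rate reaches 1."""
    return (1.0 - params.maturity_rate_intercept) / params.maturity_rate_slope


def derive_calendar(series: DailyWeather,
                    params: PhenologyParams = PhenologyParams()
                    ) -> PhenologyCalendar:
    """Compose the per-stage rules into a full, order-checked calendar.

    Any failing stage raises :class:`PhenologyError` with the stage name
    attached; an internally inconsistent calendar is never returned.
    """
    stage = "dormancy_onset"
    try:
        dorm = dormancy_onset(series, params)
        stage = "sowing"
        sowing, warns = choose_sowing_date(series, dorm, params)
        stage = "regreening"
        feb_year = series.start.year + 1
        nat = negative_accumulated_temperature(
            series,
            dt.date(series.start.year, *params.nat_start),
            dt.date(feb_year, *params.nat_end) + dt.timedelta(days=1))
        regreening = regreening_date(nat, params, february_year=feb_year)
        stage = "jointing"
        jointing = forward_stage_date(series, regreening,
                                      params.jointing_gdd, params)
        stage = "filling"
        filling = forward_stage_date(series, regreening,
                                     params.filling_gdd, params)
        stage = "maturity"
        maturity = forward_stage_date(series, regreening,
                                      maturity_gdd_threshold(params), params)
        stage = "flowering"
        flowering = flowering_date(series, filling, params)
    except (PhenologyError, WeatherError) as exc:
        raise PhenologyError(
            f"{series.county_id}: failed deriving {stage}: {exc}") from exc
    return PhenologyCalendar(
        county_id=series.county_id, sowing=sowing, dormancy_onset=dorm,
        regreening=regreening, jointing=jointing, flowering=flowering,
        filling=filling, maturity=maturity, warnings=tuple(warns))


def with_params(params: PhenologyParams, **overrides) -> PhenologyParams:
    """Convenience copy-with-overrides for sensitivity runs."""
    return replace(params, **overrides)
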