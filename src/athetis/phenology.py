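"""Degree-day accumulation, voltinism, and emergence-peak forecasting.

A day with mean temperature ``T`` contributes ``max(0, T − C)`` degree-days
toward a stage with developmental threshold ``C``; a month contributes its
mean excess times its length in days.  A stage completes when its thermal
constant ``K`` has been accumulated, and the annual number of generations is
the year's degree-day total above the whole-generation threshold divided by
the whole-generation ``K``.

Forecasts chain stages through the season.  The overwintered generation is
entered at the pupal stage — spring adults of this species emerge from
overwintered pupae — after which each generation cycles pupa →
pre-oviposition adult → egg → larva → pre-pupa.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidConstantError,
    MissingDataError,
    ResolutionMismatchError,
)
from .stages import FORECAST_CYCLE, Stage, coerce_stage
from .survival import round_half_up
from .thermal import ThermalConstants


@dataclass(frozen=True)
class TemperatureSeries:
    """Dated mean-temperature series, daily or monthly.

    Daily data carry columns ``date`` (datetime64) and ``tmean_c``; monthly
    data carry ``year``, ``month``, ``tmean_c`` and ``days_in_month``.
    """

    resolution: str  # "daily" | "monthly"
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.resolution not in ("daily", "monthly"):
            raise ValueError(f"unknown resolution {self.resolution!r}")


def daily_series(dates: Sequence, tmean_c: Sequence[float]) -> TemperatureSeries:
    """Build a daily series; dates must be strictly increasing, no duplicates."""
    d = pd.to_datetime(pd.Series(list(dates)))
    if not d.is_monotonic_increasing or d.duplicated().any():
        raise ValueError("daily dates must be strictly increasing and unique")
    frame = pd.DataFrame({"date": d.values, "tmean_c": np.asarray(tmean_c, float)})
    return TemperatureSeries("daily", frame)


def monthly_series(
    years: Sequence[int], months: Sequence[int], tmean_c: Sequence[float]
) -> TemperatureSeries:
    """Build a monthly series; month lengths follow the Gregorian calendar."""
    frame = pd.DataFrame(
        {
            "year": np.asarray(years, int),
            "month": np.asarray(months, int),
            "tmean_c": np.asarray(tmean_c, float),
        }
    )
    key = frame["year"] * 12 + frame["month"]
    if not key.is_monotonic_increasing or key.duplicated().any():
        raise ValueError("monthly entries must be strictly increasing and unique")
    frame["days_in_month"] = [
        pd.Timestamp(int(y), int(m), 1).days_in_month
        for y, m in zip(frame["year"], frame["month"])
    ]
    return TemperatureSeries("monthly", frame)


def _require(series: TemperatureSeries, resolution: str) -> pd.DataFrame:
    if series.resolution != resolution:
        raise ResolutionMismatchError(
            f"expected a {resolution} series, got {series.resolution}"
        )
    return series.data


def _check_gap_free(frame: pd.DataFrame) -> None:
    gaps = frame["date"].diff().dt.days.iloc[1:]
    if (gaps != 1).any():
        where = frame["date"].iloc[1:][gaps != 1].dt.date.tolist()
        raise MissingDataError(f"daily series has calendar gaps before {where}")


def monthly_degree_days(series: TemperatureSeries, threshold: float) -> float:
    """Degree-days above ``threshold``: Σ max(0, mean − threshold) × days."""
    frame = _require(series, "monthly")
    excess = np.maximum(0.0, frame["tmean_c"].to_numpy() - threshold)
    return float(np.sum(excess * frame["days_in_month"].to_numpy()))


def daily_degree_days(series: TemperatureSeries, threshold: float) -> pd.Series:
    """Cumulative degree-day trajectory; the last value is the total.

    Cold days contribute zero (no degree-day debt).
    """
    frame = _require(series, "daily")
    _check_gap_free(frame)
    excess = np.maximum(0.0, frame["tmean_c"].to_numpy() - threshold)
    return pd.Series(np.cumsum(excess), index=pd.DatetimeIndex(frame["date"]))


def generations_per_year(
    annual_degree_days: float, K_generation: float, ndigits: int | None = 2
) -> float:
    """Expected generations: annual degree-days over the generation K.

    Fractional generations are retained (two decimals by default); use
    :func:`complete_generations` for the integer count.
    """
    if K_generation <= 0:
        raise InvalidConstantError(f"K must be positive, got {K_generation}")
    g = annual_degree_days / K_generation
    return g if ndigits is None else round_half_up(g, ndigits)


def complete_generations(annual_degree_days: float, K_generation: float) -> int:
    """Whole generations completed within the year's heat budget."""
    return int(np.floor(generations_per_year(annual_degree_days, K_generation,
                                             ndigits=None)))


@dataclass(frozen=True)
class ForecastEvent:
    """One stage completion: generation index, stage, date, degree-days
    accumulated within the stage at completion."""

    generation: int
    stage: Stage
    date: dt.date
    cumulative_dd: float


@dataclass(frozen=True)
class PhenologyForecast:
    """Chained stage-transition forecast over a temperature series."""

    events: tuple[ForecastEvent, ...]
    complete: bool
    annual_degree_days: float = float("nan")
    generations: float = float("nan")

    @property
    def emergence_dates(self) -> list[dt.date]:
        """Adult-emergence (pupal completion) dates, one per generation."""
        return [e.date for e in self.events if e.stage is Stage.PUPA]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "generation": e.generation,
                    "stage": e.stage.value,
                    "date": e.date.isoformat(),
                    "cumulative_dd": e.cumulative_dd,
                }
                for e in self.events
            ]
        )


def forecast_emergence(
    series: TemperatureSeries,
    stage_constants: Mapping[Stage | str, ThermalConstants],
    biofix: dt.date | str,
    n_generations: int = 4,
    cycle: Sequence[Stage] = FORECAST_CYCLE,
) -> PhenologyForecast:
    """Chain stage completions forward from ``biofix`` on a daily series.

    Starting on the biofix day, each stage in ``cycle`` accumulates daily
    effective temperature above its own threshold until its thermal constant
    is reached; the crossing day is the transition date (no within-day
    interpolation) and the next stage starts the following day.  Pupal
    completions are the per-generation adult-emergence peak predictions.

    Generation 0 is the overwintered generation.  If the series ends before
    ``n_generations`` cycles complete, the forecast is returned flagged
    incomplete rather than raising.
    """
    frame = _require(series, "daily")
    _check_gap_free(frame)
    constants = {coerce_stage(k): v for k, v in stage_constants.items()}
    missing = [s.value for s in cycle if s not in constants]
    if missing:
        raise KeyError(f"no thermal constants supplied for stages {missing}")

    dates = pd.DatetimeIndex(frame["date"])
    biofix = pd.Timestamp(biofix)
    if not (dates[0] <= biofix <= dates[-1]):
        raise ValueError(
            f"biofix {biofix.date()} outside series span "
            f"[{dates[0].date()}, {dates[-1].date()}]"
        )
    temps = frame["tmean_c"].to_numpy()
    cursor = int(dates.searchsorted(biofix))

    events: list[ForecastEvent] = []
    complete = True
    for gen in range(n_generations):
        for stage in cycle:
            c = constants[stage]
            cum = 0.0
            day = cursor
            while day < len(temps):
                cum += max(0.0, temps[day] - c.C)
                if cum >= c.K:
                    events.append(
                        ForecastEvent(gen, stage, dates[day].date(), cum)
                    )
                    cursor = day + 1
                    break
                day += 1
            else:
                complete = False
                return PhenologyForecast(tuple(events), complete)
    return PhenologyForecast(tuple(events), complete)


def annual_forecast(
    series: TemperatureSeries,
    stage_constants: Mapping[Stage | str, ThermalConstants],
    generation_constants: ThermalConstants,
    biofix: dt.date | str,
    n_generations: int = 4,
) -> PhenologyForecast:
    """Emergence forecast plus the annual degree-day and voltinism summary."""
    base = forecast_emergence(series, stage_constants, biofix, n_generations)
    total = float(daily_degree_days(series, generation_constants.C).iloc[-1])
    return PhenologyForecast(
        events=base.events,
        complete=base.complete,
        annual_degree_days=total,
        generations=generations_per_year(total, generation_constants.K),
    )
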