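"""CSV/JSON readers and writers for the pipeline's tabular interchange.

All tabular inputs are small UTF-8 CSVs with header rows; nested results
(survival curves, forecasts, provenance) are JSON.  Validation errors name
the offending line and field.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from .errors import InputFormatError
from .life_table import LifeTable
from .phenology import (
    PhenologyForecast,
    TemperatureSeries,
    daily_series,
    monthly_series,
)
from .stages import (
    Stage,
    VALID_OUTCOME_LABELS,
    VALID_STAGE_LABELS,
)
from .survival import SurvivalCurve, round_half_up
from .thermal import RECORD_COLUMNS, ThermalConstants


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputFormatError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputFormatError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise InputFormatError(f"{path}: no data rows")
    return frame


def read_rearing_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a rearing-record CSV (one row per individual-stage)."""
    frame = _read_csv(path, RECORD_COLUMNS)
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        if row["stage"] not in VALID_STAGE_LABELS:
            raise InputFormatError(
                f"{path}: line {line}, field 'stage': unknown label "
                f"{row['stage']!r}"
            )
        if row["outcome"] not in VALID_OUTCOME_LABELS:
            raise InputFormatError(
                f"{path}: line {line}, field 'outcome': unknown label "
                f"{row['outcome']!r}"
            )
        if not pd.notna(row["temperature_c"]):
            raise InputFormatError(
                f"{path}: line {line}, field 'temperature_c': not a number"
            )
        if row["outcome"] == "completed" and not row["duration_days"] > 0:
            raise InputFormatError(
                f"{path}: line {line}, field 'duration_days': completed "
                f"record must have positive duration"
            )
    return frame


def write_rearing_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, list(RECORD_COLUMNS)].to_csv(path, index=False)


SURVIVAL_COLUMNS = ("temperature_c", "stage", "n_entering", "n_advancing")


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    frame = _read_csv(path, SURVIVAL_COLUMNS)
    for i, row in frame.iterrows():
        line = i + 2
        if row["n_advancing"] > row["n_entering"]:
            raise InputFormatError(
                f"{path}: line {line}, field 'n_advancing': exceeds n_entering"
            )
        if row["n_entering"] < 0 or row["n_advancing"] < 0:
            raise InputFormatError(
                f"{path}: line {line}: negative count"
            )
    return frame


def read_weather_csv(path: str | Path) -> TemperatureSeries:
    """Read a weather CSV, daily (date,tmean_c) or monthly (year,month,tmean_c)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputFormatError(f"{path}: file is empty") from None
    cols = set(frame.columns)
    if {"date", "tmean_c"} <= cols:
        return daily_series(frame["date"], frame["tmean_c"])
    if {"year", "month", "tmean_c"} <= cols:
        return monthly_series(frame["year"], frame["month"], frame["tmean_c"])
    raise InputFormatError(
        f"{path}: expected daily columns (date, tmean_c) or monthly "
        f"(year, month, tmean_c); got {sorted(cols)}"
    )


def write_weather_csv(series: TemperatureSeries, path: str | Path) -> None:
    if series.resolution == "daily":
        out = series.data.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
    else:
        series.data.loc[:, ["year", "month", "tmean_c"]].to_csv(path, index=False)


def write_constants_csv(fits: Iterable[ThermalConstants], path: str | Path) -> None:
    from .thermal import constants_frame

    constants_frame(fits).to_csv(path, index=False)


def read_constants_csv(path: str | Path) -> dict[Stage, ThermalConstants]:
    frame = _read_csv(path, ("stage", "C", "K"))
    out: dict[Stage, ThermalConstants] = {}
    for i, row in frame.iterrows():
        if row["stage"] not in VALID_STAGE_LABELS:
            raise InputFormatError(
                f"{path}: line {i + 2}, field 'stage': unknown label "
                f"{row['stage']!r}"
            )
        stage = Stage(row["stage"])
        out[stage] = ThermalConstants(
            stage=stage,
            C=float(row["C"]),
            Sc=float(row.get("Sc", float("nan"))),
            K=float(row["K"]),
            Sk=float(row.get("Sk", float("nan"))),
            r=float(row.get("r", float("nan"))),
            n=int(row.get("n", 0)),
        )
    return out


def write_curve_json(curve: SurvivalCurve, optimum: float | None,
                     path: str | Path) -> None:
    payload = {
        "coefficients": list(curve.coefficients),
        "fit_range": list(curve.fit_range),
        "optimum_c": optimum,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_life_table_csv(table: LifeTable, path: str | Path) -> None:
    """One row per stage, then a footer block with the scalar summaries."""
    lines = ["stage,n_entering,survival_pct,arrested_pct"]
    for row in table.rows:
        lines.append(
            f"{row.stage},{row.n_entering:.4f},"
            f"{round_half_up(100 * row.survival_fraction):.2f},"
            f"{round_half_up(100 * row.arrested_fraction):.2f}"
        )
    lines += [
        "",
        f"temperature_c,{table.temperature:g}",
        f"initial_eggs,{table.initial_eggs:g}",
        f"female_fraction,{table.female_fraction:g}",
        f"eggs_per_female,{table.eggs_per_female:g}",
        f"trend_index,{round_half_up(table.trend_index):.2f}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def life_table_dict(table: LifeTable) -> dict:
    return {
        "temperature_c": table.temperature,
        "initial_eggs": table.initial_eggs,
        "rows": [
            {
                "stage": r.stage,
                "n_entering": r.n_entering,
                "survival_fraction": r.survival_fraction,
                "arrested_fraction": r.arrested_fraction,
            }
            for r in table.rows
        ],
        "female_fraction": table.female_fraction,
        "eggs_per_female": table.eggs_per_female,
        "trend_index": table.trend_index,
    }


def write_life_tables_json(tables: Iterable[LifeTable], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([life_table_dict(t) for t in tables], indent=2)
    )


def write_forecast_json(forecast: PhenologyForecast, path: str | Path) -> None:
    payload = {
        "annual_degree_days": None
        if pd.isna(forecast.annual_degree_days)
        else forecast.annual_degree_days,
        "generations": None
        if pd.isna(forecast.generations)
        else forecast.generations,
        "complete": forecast.complete,
        "events": [
            {
                "generation": e.generation,
                "stage": e.stage.value,
                "date": e.date.isoformat(),
                "cumulative_dd": e.cumulative_dd,
            }
            for e in forecast.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_forecast_csv(forecast: PhenologyForecast, path: str | Path) -> None:
    forecast.events_frame().to_csv(path, index=False)


def write_provenance(
    path: str | Path,
    command: str,
    inputs: Mapping[str, str],
    parameters: Mapping[str, object],
    seed: int | None,
) -> None:
    """Machine-readable record of what produced a set of outputs."""
    payload = {
        "tool": "athetis",
        "version": __version__,
        "command": command,
        "timestamp": dt.datetime.now(dt.timezone.utc).isoformat(),
        "inputs": dict(inputs),
        "parameters": {k: repr(v) if isinstance(v, Path) else v
                       for k, v in parameters.items()},
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
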