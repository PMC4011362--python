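"""Law-of-effective-temperature estimation.

Ectotherm development above a stage-specific threshold temperature ``C``
proceeds at a rate proportional to the thermal excess, so the duration ``D``
of a stage at constant temperature ``T`` obeys

    D * (T - C) = K        equivalently        T = C + K * V,   V = 1 / D,

where ``K`` (degree-days) is the effective accumulative temperature (thermal
constant) of the stage.  Regressing treatment temperature on mean
developmental rate therefore yields ``C`` as the intercept and ``K`` as the
slope, each with an ordinary least-squares standard error.  Fits use one
point per constant-temperature treatment (the treatment mean rate), matching
the treatment-level degrees of freedom conventional in this literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    BelowThresholdError,
    DegenerateDesignError,
    EmptyInputError,
    NonPhysicalFitError,
)
from .stages import Outcome, Stage, coerce_stage

#: Canonical rearing-record column names.
RECORD_COLUMNS = (
    "individual_id",
    "stage",
    "temperature_c",
    "duration_days",
    "outcome",
)


@dataclass(frozen=True)
class TreatmentSummary:
    """Mean development of one stage at one constant temperature.

    ``rate`` is the developmental rate V = 1 / mean duration (per day).
    """

    temperature: float
    stage: Stage
    mean_duration: float
    n_completed: int

    @property
    def rate(self) -> float:
        return 1.0 / self.mean_duration


@dataclass(frozen=True)
class ThermalConstants:
    """Fitted threshold temperature and thermal constant for one stage.

    Attributes
    ----------
    C, Sc : developmental threshold temperature (°C) and its OLS standard
        error; Sc is NaN when only two treatments leave no residual df.
    K, Sk : effective accumulative temperature (degree-days) and its OLS
        standard error.
    r : Pearson correlation between developmental rate and temperature.
    n : number of constant-temperature treatments used in the fit.
    """

    stage: Stage
    C: float
    Sc: float
    K: float
    Sk: float
    r: float
    n: int


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check a rearing-record frame for the canonical columns and values."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"rearing records missing columns {missing}")
    bad = records.loc[
        (records["outcome"] == Outcome.COMPLETED.value)
        & ~(records["duration_days"] > 0)
    ]
    if len(bad):
        raise ValueError(
            f"{len(bad)} completed records have non-positive durations"
        )
    return records


def summarize_treatments(
    records: pd.DataFrame, stage: Stage | str
) -> list[TreatmentSummary]:
    """Mean duration and rate per constant-temperature treatment.

    Only individuals that completed the stage contribute; deaths and
    low-temperature developmental arrest are excluded (an arrested larva
    carries no information about the completion time of the stage).

    Raises
    ------
    EmptyInputError
        If no temperature has any completed record for ``stage``.
    """
    stage = coerce_stage(stage)
    sub = records.loc[
        (records["stage"] == stage.value)
        & (records["outcome"] == Outcome.COMPLETED.value)
    ]
    if sub.empty:
        raise EmptyInputError(
            f"no completed records for stage {stage.value!r} at any temperature"
        )
    out: list[TreatmentSummary] = []
    for temp, grp in sub.groupby("temperature_c", sort=True):
        out.append(
            TreatmentSummary(
                temperature=float(temp),
                stage=stage,
                mean_duration=float(grp["duration_days"].mean()),
                n_completed=int(len(grp)),
            )
        )
    return out


def fit_thermal_constants(
    summaries: Iterable[TreatmentSummary],
) -> ThermalConstants:
    """Fit T = C + K·V by ordinary least squares over treatment means.

    Parameters
    ----------
    summaries
        One :class:`TreatmentSummary` per constant-temperature treatment,
        all for the same stage, with at least two distinct temperatures.

    Returns
    -------
    ThermalConstants
        Intercept C, slope K, their standard errors, the Pearson r of
        (V, T), and the number of treatments.  With exactly two treatments
        the line is exactly determined and Sc/Sk are NaN.

    Raises
    ------
    DegenerateDesignError
        Fewer than two distinct temperatures.
    NonPhysicalFitError
        Fitted K <= 0 (development slowing with warmth is outside the
        model's domain of validity).
    """
    summaries = sorted(summaries, key=lambda s: s.temperature)
    if not summaries:
        raise DegenerateDesignError("no treatment summaries supplied")
    stage = summaries[0].stage
    temps = np.array([s.temperature for s in summaries], dtype=float)
    rates = np.array([s.rate for s in summaries], dtype=float)
    if np.unique(temps).size < 2:
        raise DegenerateDesignError(
            f"stage {stage.value!r}: need >= 2 distinct temperatures, "
            f"got {np.unique(temps).size}"
        )
    if np.any(rates <= 0):
        raise NonPhysicalFitError(f"stage {stage.value!r}: non-positive rate")

    n = temps.size
    if n == 2:
        K = (temps[1] - temps[0]) / (rates[1] - rates[0])
        C = temps[0] - K * rates[0]
        r = 1.0 if K > 0 else -1.0
        Sc = Sk = float("nan")
    else:
        res = stats.linregress(rates, temps)
        C, K = float(res.intercept), float(res.slope)
        r = float(res.rvalue)
        Sk = float(res.stderr)
        Sc = float(res.intercept_stderr)
    if K <= 0:
        raise NonPhysicalFitError(
            f"stage {stage.value!r}: fitted K = {K:.3f} <= 0"
        )
    return ThermalConstants(stage=stage, C=float(C), Sc=Sc, K=float(K), Sk=Sk,
                            r=r, n=int(n))


def fit_all_stages(
    records: pd.DataFrame, stages: Sequence[Stage | str] | None = None
) -> list[ThermalConstants]:
    """Fit thermal constants for every stage present (or a chosen subset)."""
    validate_records(records)
    if stages is None:
        present = records.loc[
            records["outcome"] == Outcome.COMPLETED.value, "stage"
        ].unique()
        stages = [s for s in Stage if s.value in set(present)]
    return [
        fit_thermal_constants(summarize_treatments(records, s)) for s in stages
    ]


def predict_duration(constants: ThermalConstants, temperature: float) -> float:
    """Predicted stage duration K / (T − C) in days at ``temperature`` °C.

    Raises
    ------
    BelowThresholdError
        At or below the threshold no development occurs and the duration
        diverges.
    """
    excess = temperature - constants.C
    if excess <= 0:
        raise BelowThresholdError(
            f"temperature {temperature} °C is at or below the threshold "
            f"{constants.C:.2f} °C for stage {constants.stage.value!r}"
        )
    return constants.K / excess


def constants_frame(fits: Iterable[ThermalConstants]) -> pd.DataFrame:
    """Tabulate fits as a DataFrame (stage, C, Sc, K, Sk, r, n)."""
    return pd.DataFrame(
        [
            {
                "stage": f.stage.value,
                "C": f.C,
                "Sc": f.Sc,
                "K": f.K,
                "Sk": f.Sk,
                "r": f.r,
                "n": f.n,
            }
            for f in fits
        ]
    )


def residual_sum_of_squares(
    constants: ThermalConstants, summaries: Iterable[TreatmentSummary]
) -> float:
    """RSS of temperature about the fitted line (diagnostic)."""
    return float(
        sum(
            (s.temperature - (constants.C + constants.K * s.rate)) ** 2
            for s in summaries
        )
    )


def undefined_se(value: float) -> bool:
    """True when a standard error is the NaN marker (0 residual df)."""
    return math.isnan(value)
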