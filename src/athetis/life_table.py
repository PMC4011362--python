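"""Experimental population life tables and the index of population trend.

Starting from a nominal cohort of 100 live eggs, the cohort is propagated
multiplicatively through the stage survival fractions observed at one
rearing temperature.  The index of population trend

    I = (Π stage survivals) × female fraction × eggs per female

is the expected number of next-generation eggs per current-generation egg:
I > 1 means a growing population, I < 1 a declining one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import IncompleteTableError

#: Core cohort stages a complete life table must cover, in order.  The
#: larval phase may be represented by one pooled stage or several instars,
#: and the adult row is the pupa→adult emergence transition.
_EGG = "egg"
_PREPUPA = "prepupa"
_PUPA = "pupa"


@dataclass(frozen=True)
class LifeTableRow:
    stage: str
    n_entering: float
    survival_fraction: float
    arrested_fraction: float = 0.0


@dataclass(frozen=True)
class LifeTable:
    """Stage-structured cohort table for one rearing temperature."""

    temperature: float
    initial_eggs: float
    rows: tuple[LifeTableRow, ...]
    female_fraction: float
    eggs_per_female: float
    trend_index: float = field(default=0.0)

    @property
    def final_adults(self) -> float:
        last = self.rows[-1]
        return last.n_entering * last.survival_fraction


def _is_larval(label: str) -> bool:
    return label.startswith("instar") or label.startswith("larva")


def _is_adult(label: str) -> bool:
    return label.startswith("adult") or label in ("emergence", "preoviposition")


def _validate_stage_order(labels: list[str]) -> None:
    """The map must cover egg → larva(e) → prepupa → pupa → adult, in order."""
    required_markers = [
        ("egg", lambda s: s == _EGG),
        ("larva", _is_larval),
        ("prepupa", lambda s: s == _PREPUPA),
        ("pupa", lambda s: s == _PUPA),
        ("adult", _is_adult),
    ]
    pos = 0
    for name, match in required_markers:
        while pos < len(labels) and not match(labels[pos]):
            pos += 1
        if pos == len(labels):
            raise IncompleteTableError(
                f"life table missing required stage {name!r} "
                f"(got stages {labels})"
            )
        pos += 1


def trend_index(
    stage_survivals: Iterable[float],
    female_fraction: float,
    eggs_per_female: float,
) -> float:
    """Closed-form index of population trend."""
    prod = 1.0
    for s in stage_survivals:
        prod *= s
    return prod * female_fraction * eggs_per_female


def build_life_table(
    stage_survivals: Mapping[str, float],
    female_fraction: float,
    eggs_per_female: float,
    initial_eggs: float = 100.0,
    temperature: float = float("nan"),
    arrested_fractions: Mapping[str, float] | None = None,
) -> LifeTable:
    """Propagate a cohort of ``initial_eggs`` through stage survivals.

    Parameters
    ----------
    stage_survivals
        Ordered mapping stage label → fraction surviving that stage, in
        developmental order; must cover egg, at least one larval stage,
        prepupa, pupa, and an adult-emergence stage.  Developmental arrest
        (mature larvae failing to pupate at low temperature) is mortality at
        the pre-pupal transition; the arrested share may be reported
        separately via ``arrested_fractions``.
    female_fraction, eggs_per_female
        Sex ratio (proportion female among emerging adults) and mean
        fecundity per female.
    """
    labels = list(stage_survivals)
    _validate_stage_order(labels)
    if not 0.0 <= female_fraction <= 1.0:
        raise ValueError("female_fraction must lie in [0, 1]")
    if initial_eggs <= 0:
        raise ValueError("initial_eggs must be positive")
    arrested_fractions = arrested_fractions or {}

    rows: list[LifeTableRow] = []
    n = float(initial_eggs)
    for label in labels:
        frac = float(stage_survivals[label])
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"survival fraction {frac} for {label!r} outside [0, 1]")
        rows.append(
            LifeTableRow(
                stage=label,
                n_entering=n,
                survival_fraction=frac,
                arrested_fraction=float(arrested_fractions.get(label, 0.0)),
            )
        )
        n *= frac

    index = trend_index(stage_survivals.values(), female_fraction, eggs_per_female)
    return LifeTable(
        temperature=float(temperature),
        initial_eggs=float(initial_eggs),
        rows=tuple(rows),
        female_fraction=float(female_fraction),
        eggs_per_female=float(eggs_per_female),
        trend_index=index,
    )


def trend_index_by_cohort_walk(table: LifeTable) -> float:
    """Brute-force I: walk the cohort, count next-generation eggs per egg.

    Independent of the closed-form product; used as an internal consistency
    oracle.
    """
    n = table.initial_eggs
    for row in table.rows:
        n = n * row.survival_fraction
    females = n * table.female_fraction
    next_eggs = females * table.eggs_per_female
    return next_eggs / table.initial_eggs


def compare_trend_indices(tables: Iterable[LifeTable]) -> list[LifeTable]:
    """Rank life tables by trend index, descending; ties by temperature
    ascending."""
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("ranking needs at least two life tables")
    return sorted(tables, key=lambda t: (-t.trend_index, t.temperature))
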