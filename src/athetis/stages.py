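"""Life-stage and outcome vocabularies for *Athetis lepigone* rearing data.

The moth passes through egg, five or six larval instars, a cocoon-enclosed
pre-pupa, pupa, and adult.  ``GENERATION`` labels the composite egg-to-first-
oviposition interval that the whole-generation thermal constants describe.
"""

from __future__ import annotations

import enum


class Stage(str, enum.Enum):
    """Enumerated life stages appearing in rearing records."""

    EGG = "egg"
    INSTAR1 = "instar1"
    INSTAR2 = "instar2"
    INSTAR3 = "instar3"
    INSTAR4 = "instar4"
    INSTAR5 = "instar5"
    INSTAR6 = "instar6"
    LARVA_TOTAL = "larva_total"
    PREPUPA = "prepupa"
    PUPA = "pupa"
    PREOVIPOSITION = "preoviposition"
    ADULT_FEMALE = "adult_female"
    ADULT_MALE = "adult_male"
    GENERATION = "generation"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Outcome(str, enum.Enum):
    """Fate of one individual in one stage."""

    COMPLETED = "completed"
    DIED = "died"
    ARRESTED = "arrested"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Developmental chain simulated per individual, in order.
REARING_CHAIN: tuple[Stage, ...] = (
    Stage.EGG,
    Stage.LARVA_TOTAL,
    Stage.PREPUPA,
    Stage.PUPA,
    Stage.PREOVIPOSITION,
)

#: Stage cycle used when forecasting field generations.  The overwintered
#: generation is picked up at the pupal stage (spring adults emerge from
#: overwintered pupae); subsequent generations cycle through the same order.
FORECAST_CYCLE: tuple[Stage, ...] = (
    Stage.PUPA,
    Stage.PREOVIPOSITION,
    Stage.EGG,
    Stage.LARVA_TOTAL,
    Stage.PREPUPA,
)

VALID_STAGE_LABELS = frozenset(s.value for s in Stage)
VALID_OUTCOME_LABELS = frozenset(o.value for o in Outcome)


def coerce_stage(label: "Stage | str") -> Stage:
    """Return the :class:`Stage` for ``label``, raising ``ValueError`` on junk."""
    if isinstance(label, Stage):
        return label
    try:
        return Stage(str(label))
    except ValueError:
        raise ValueError(
            f"unknown stage label {label!r}; expected one of "
            f"{sorted(VALID_STAGE_LABELS)}"
        ) from None
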