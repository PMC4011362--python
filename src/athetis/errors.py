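"""Exception hierarchy for the athetis pipeline."""


class AthetisError(Exception):
    """Base class for all pipeline errors."""


class EmptyInputError(AthetisError):
    """No usable (completed) records were found for a requested stage."""


class DegenerateDesignError(AthetisError):
    """Too few distinct temperatures to fit the effective-temperature line."""


class NonPhysicalFitError(AthetisError):
    """A fitted thermal constant violates physics (K <= 0)."""


class BelowThresholdError(AthetisError):
    """Requested temperature is at or below the developmental threshold."""


class UndefinedRateError(AthetisError):
    """Survival rate requested with zero individuals entering the stage."""


class InconsistentCountError(AthetisError):
    """More individuals advanced than entered a stage."""


class UnderdeterminedFitError(AthetisError):
    """Fewer observations than parameters for the survival polynomial."""


class NoOptimumError(AthetisError):
    """The fitted survival curve has no interior maximum on its range."""


class IncompleteTableError(AthetisError):
    """A life table is missing one of the required cohort stages."""


class ResolutionMismatchError(AthetisError):
    """A daily operation received a monthly series or vice versa."""


class MissingDataError(AthetisError):
    """A daily temperature series has calendar gaps."""


class InvalidConstantError(AthetisError):
    """A thermal constant passed to phenology is non-positive."""


class InputFormatError(AthetisError):
    """A CSV input failed validation; message carries line number and field."""
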