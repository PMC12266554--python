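"""Exception hierarchy shared across the package.

Every contract violation raises a subclass of :class:`NutrailError` so callers
can distinguish domain errors from programming errors.
"""


class NutrailError(Exception):
    """Base class for all package-specific errors."""


class InvalidCompositionError(NutrailError):
    """Diet fractions violate the 50% protein+lipid recipe constraint."""


class DomainError(NutrailError):
    """An argument is outside its mathematical domain (negative mass, etc.)."""


class UndefinedRatioError(NutrailError):
    """A protein:lipid ratio is requested with zero lipid in the denominator."""


class DegenerateRailError(NutrailError):
    """A food rail has zero protein or zero lipid fraction where both are needed."""


class InsufficientDataError(NutrailError):
    """Too few observations or groups for the requested statistic."""


class EmptyCageError(NutrailError):
    """Per-capita intake requested for a cage with no live bees."""


class SuspectRecordError(NutrailError):
    """A dish gained more mass than the measurement-noise tolerance allows."""


class LookupError_(NutrailError):
    """A diet name could not be resolved against the provided diet table."""


class ConfigError(NutrailError):
    """An experiment design or simulation configuration is invalid."""


class DishExhaustedError(NutrailError):
    """Simulated demand exceeded the food mass provided in a dish."""


class DegenerateModelError(NutrailError):
    """A statistical model cannot be fit (e.g. survival data with no events)."""
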