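"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`ObesityDosingError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class ObesityDosingError(Exception):
    """Base class for all domain errors."""


class InvalidMeasurementError(ObesityDosingError):
    """A physical measurement (height, weight, BMI input) is non-positive."""


class OutOfRangeError(ObesityDosingError):
    """An age falls outside the growth-reference table's covered interval."""


class NotEligibleError(ObesityDosingError):
    """Patient is outside the initiative's scope (under 2 years of age)."""


class ConfigurationError(ObesityDosingError):
    """A tunable parameter (cofactor, sigma, goal) is outside its valid range."""


class SchemaError(ObesityDosingError):
    """A formulary or config document fails structural validation."""


class DataIntegrityError(ObesityDosingError):
    """Inputs are mutually inconsistent (e.g. per-kg order without a weight)."""


class NotGovernedError(ObesityDosingError):
    """An order's drug has no rule in the formulary."""


class EmptyChartError(ObesityDosingError):
    """A control chart was requested for an empty series."""


class UndefinedRateError(ObesityDosingError):
    """A rate was requested with a zero denominator."""


class GenerationError(ObesityDosingError):
    """The synthetic-cohort generator cannot satisfy its specification."""
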