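"""Exception hierarchy for the adiposcan pipeline."""


class AdiposcanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AdiposcanError):
    """Invalid cohort/pipeline configuration; the message names the field."""


class SchemaError(AdiposcanError):
    """A record, table or model is missing a required variable or column."""


class DomainError(AdiposcanError, ValueError):
    """An input value is outside its physical/mathematical domain."""


class LandmarkDetectionError(AdiposcanError):
    """A body-profile landmark could not be located; the message names it."""


class DegenerateVarianceError(AdiposcanError):
    """A variable has (numerically) zero variance, so it cannot be
    standardized or carry a principal-component loading."""
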