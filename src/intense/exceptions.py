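"""Exception hierarchy for the intense package."""


class IntenseError(Exception):
    """Base class for all package errors."""


class SchemaError(IntenseError):
    """A factor schema is internally inconsistent."""


class CohortValidationError(IntenseError):
    """A cohort table violates its schema (missing column, bad level, ...)."""


class DegenerateDataError(IntenseError):
    """Input data is degenerate for the requested operation (constant column,
    fewer distinct points than clusters, ...)."""


class ConfigError(IntenseError):
    """A run or generator configuration is invalid."""
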