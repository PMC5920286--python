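"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors (2), data/schema
errors (3), numerical/fit errors (4).
"""


class MorbisimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MorbisimError):
    """Invalid registry, condition set, or run configuration."""


class DomainError(MorbisimError, ValueError):
    """Scalar argument outside its mathematical domain."""


class SchemaError(MorbisimError):
    """A required covariate or column is missing; names the offender."""


class ScheduleError(MorbisimError):
    """Mortality schedule incomplete or individual beyond its terminal age."""


class TableCoverageError(MorbisimError):
    """Allocation table does not cover a required cell."""


class DegenerateFitError(MorbisimError):
    """Transition outcome constant in the panel; no model can be fitted."""


class InputError(MorbisimError):
    """Mismatched or empty inputs to a computation."""
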