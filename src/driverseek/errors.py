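"""Exception hierarchy.

Every invariant on an input table is enforced at read/validation time and
raises one of these named errors; downstream modules assume validated data.
"""


class DriverseekError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DriverseekError, ValueError):
    """An input table or parameter violates a documented invariant."""


class LibraryError(ValidationError):
    """Malformed sgRNA library table."""


class CountsError(ValidationError):
    """Malformed sgRNA count matrix."""


class CohortError(ValidationError):
    """Malformed or inconsistent clinical cohort tables."""


class MatrixError(ValidationError):
    """Malformed essentiality (gene-effect or essential-call) matrix."""


class ScreenError(DriverseekError):
    """Screen scoring cannot proceed (e.g. no negative controls)."""


class SurvivalError(DriverseekError):
    """Survival analysis cannot proceed (e.g. no events, constant expression)."""


class ConfigError(ValidationError):
    """Invalid or incomplete run configuration."""
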