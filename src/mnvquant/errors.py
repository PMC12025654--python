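"""Exception hierarchy shared across the package.

All exceptions derive from :class:`MnvQuantError` so callers can catch
package-level failures with a single except clause while still
distinguishing validation problems from I/O or numerical ones.
"""


class MnvQuantError(Exception):
    """Base class for all package errors."""


class ParameterError(MnvQuantError, ValueError):
    """A parameter is outside its documented range."""


class FormatError(MnvQuantError, ValueError):
    """An input file has an unsupported or inconsistent format."""


class SchemaError(MnvQuantError, ValueError):
    """A tabular input does not match the expected column schema."""


class CohortValidationError(SchemaError):
    """Cohort rows violate value constraints; offending rows are listed."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class DegenerateInputError(MnvQuantError, ValueError):
    """Input is technically valid but carries no usable signal."""


class InsufficientScalesError(MnvQuantError, ValueError):
    """Too few box sizes available for a box-counting slope."""


class SingularDesignError(MnvQuantError, ValueError):
    """Regression design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class SeparationError(MnvQuantError, RuntimeError):
    """Logistic likelihood diverges (complete or quasi-separation)."""


class ContractViolationError(MnvQuantError, RuntimeError):
    """An internal contract (e.g. skeleton thinness) was violated."""
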