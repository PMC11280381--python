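"""Exception hierarchy.

Exit-code mapping used by the command-line interface:
configuration errors -> 2, data errors -> 3, numerical errors -> 4.
"""


class QSARFlowError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(QSARFlowError):
    """Invalid run configuration (bad split fraction, missing section, ...)."""

    exit_code = 2


class DataError(QSARFlowError):
    """Invalid or malformed input data."""

    exit_code = 3


class ParseError(DataError):
    """A cell or field could not be parsed; names the offending row/column."""


class ValidationError(DataError):
    """A dataset-level invariant is violated (duplicate ids, ragged rows...)."""


class PruneError(DataError):
    """Descriptor pruning removed every column."""

    def __init__(self, message, removal_log=None):
        super().__init__(message)
        self.removal_log = removal_log or []


class SelectionError(DataError):
    """Correlation-based descriptor selection produced an empty subset."""


class FixtureLookupError(DataError):
    """Unknown fixture name; carries the list of valid names."""


class NumericalError(QSARFlowError):
    """Numerically degenerate problem."""

    exit_code = 4


class SingularDesignError(NumericalError):
    """Rank-deficient descriptor matrix; names the offending columns."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns else []


class SizeError(NumericalError):
    """Too few records for the requested fit or cross-validation."""


class DegenerateResponseError(NumericalError):
    """Zero-variance response where variance is required."""


class UndefinedCorrelationError(NumericalError):
    """Correlation undefined (constant predictions or observations)."""


class FoldError(NumericalError):
    """A leave-one-out fold became singular; names the left-out record."""
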