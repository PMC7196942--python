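"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`CasusError` so callers can catch the package's
failures with one clause; validation problems (bad input tables, inconsistent
records) are distinguished from domain errors (arguments outside a statistic's
domain) and from missing-data conditions, which are never silently imputed.
"""


class CasusError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CasusError, ValueError):
    """Structurally invalid input: duplicate rows, inconsistent records, bad schema."""


class DomainError(CasusError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class MissingDataError(CasusError, ValueError):
    """Required measurement absent; the pipeline refuses to impute silently."""


class FitError(CasusError, ValueError):
    """Regression cannot be fitted (rank deficiency, too few points)."""


class CalibrationError(CasusError, ValueError):
    """Synthetic event-model calibration has no solution under the given config."""
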