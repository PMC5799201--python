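"""Exception taxonomy for summr.

All package errors derive from :class:`SummrError` so callers can catch the
whole family; the finer classes distinguish input-format problems from
statistical/estimation failures and configuration mistakes.
"""


class SummrError(Exception):
    """Base class for all summr errors."""


class FormatError(SummrError):
    """A summary-statistic table violates the expected layout or a field invariant."""


class DuplicateSnpError(FormatError):
    """The same rsID appears more than once where uniqueness is required."""


class VocabularyError(SummrError):
    """A label is outside the controlled vocabulary (subtype, scenario name, method)."""


class DomainError(SummrError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InputError(SummrError):
    """A structured input (e.g. an LD matrix) is malformed."""


class EstimationError(SummrError):
    """An estimator cannot produce a result on the given instrument set."""


class InsufficientDataError(EstimationError):
    """Too few instruments for the requested estimator."""


class CollinearityError(EstimationError):
    """Degenerate design: the regression problem has no unique solution."""


class ConfigError(SummrError):
    """A run or simulation configuration is invalid."""
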