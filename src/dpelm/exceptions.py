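"""Exception hierarchy shared across the package.

Everything derives from :class:`DPELMError` so callers can catch one base
class; the leaves distinguish bad user input from numerical breakdown.
"""


class DPELMError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(DPELMError, ValueError):
    """Input violates a documented precondition (non-finite values, empty data...)."""


class ShapeError(DPELMError, ValueError):
    """Array dimensions are inconsistent with the operation."""


class DomainError(DPELMError, ValueError):
    """A value lies at or near a pole / outside the domain of an elementwise map."""


class UnsupportedActivationError(DPELMError, KeyError):
    """Requested activation is not registered or lacks an inverse."""


class ParseError(DPELMError, ValueError):
    """A delimited-text cell could not be parsed as a number."""


class MissingDataError(DPELMError, ValueError):
    """Dataset contains missing values; no imputation is performed."""


class DegenerateDatasetError(DPELMError, ValueError):
    """Dataset has fewer than two distinct classes."""


class InfeasibleSplitError(DPELMError, ValueError):
    """Requested train/test split would leave a class empty in one partition."""


class InfeasibleParameterError(DPELMError, ValueError):
    """Generator or trainer parameters violate a structural requirement."""


class DegenerateDrawError(DPELMError, RuntimeError):
    """Random initialization failed to produce a full-rank matrix within the retry budget."""


class NumericError(DPELMError, ArithmeticError):
    """A training stage produced non-finite intermediates."""


class ConfigurationError(DPELMError, ValueError):
    """Run configuration is inconsistent or names an unknown component."""
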