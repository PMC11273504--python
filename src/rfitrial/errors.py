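"""Exception types shared across the package."""


class RFITrialError(Exception):
    """Base class for all package errors."""


class ConfigError(RFITrialError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(RFITrialError, ValueError):
    """An input outside the mathematical domain of an operation."""


class SingularDesignError(RFITrialError, ValueError):
    """A rank-deficient regression design; the message names collinear columns."""


class UndefinedCorrelationError(RFITrialError, ValueError):
    """Correlation requested for a constant (zero-variance) vector."""


class DegenerateAgreementError(RFITrialError, ValueError):
    """Kappa undefined because chance agreement is 1 (both raters constant)."""


class IdMismatchError(RFITrialError, ValueError):
    """Two collections that must share an id set do not."""


class StageError(RFITrialError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
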