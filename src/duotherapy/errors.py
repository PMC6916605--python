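"""Package exception hierarchy."""


class DuotherapyError(Exception):
    """Base class for package errors."""


class ConfigError(DuotherapyError, ValueError):
    """Invalid configuration value or combination."""


class ContractViolation(DuotherapyError, RuntimeError):
    """An operation received input violating its stated precondition."""


class SeparationError(DuotherapyError, RuntimeError):
    """Perfect separation in the propensity model.

    Carries the names of the offending covariates in ``covariates``.
    """

    def __init__(self, message, covariates=()):
        super().__init__(message)
        self.covariates = list(covariates)
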