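"""Package-wide exception types."""


class MetfaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetfaError):
    """Invalid simulation or analysis configuration."""


class InputError(MetfaError):
    """Invalid data passed to an operation (violated precondition)."""


class CensoredStageError(MetfaError):
    """Weather series ends before a growth-stage threshold is reached."""

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"growth stage '{stage}' not reached before end of weather series")


class EmergenceUndefinedError(MetfaError):
    """No rain ever fell after sowing, so emergence cannot be dated."""


class FitError(MetfaError):
    """Model fitting failed (non-convergence, singular design, ...)."""


class PedigreeError(MetfaError):
    """Malformed pedigree (parse failure or cycle)."""
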