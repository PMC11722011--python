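"""Exception hierarchy shared by all pipeline stages."""


class NmrMapError(Exception):
    """Base class for all package errors."""


class ValidationError(NmrMapError):
    """Input violates a documented invariant (bad file, duplicate assignment...)."""


class InsufficientDataError(NmrMapError):
    """Too few observations for the requested statistic."""


class FitError(NmrMapError):
    """A model fit failed or is unidentifiable."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class NormalizationError(NmrMapError):
    """PRE normalization could not establish a reference set."""


class ConfigurationError(NmrMapError):
    """Thresholds/ranges supplied by the user do not cover the data."""


class EmptyStructureError(ValidationError):
    """A coordinate file contained no ATOM records."""
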