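"""Exception hierarchy for the ramanmargin package."""


class RamanMarginError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RamanMarginError):
    """Invalid or inconsistent configuration values."""


class ParameterError(RamanMarginError):
    """Invalid parameter passed to a processing operation."""


class CalibrationError(RamanMarginError):
    """Wavenumber calibration could not be established."""


class NumericalError(RamanMarginError):
    """A numerical condition required by an operation was violated."""


class NormalizationError(RamanMarginError):
    """Spectrum cannot be normalized (e.g. zero variance)."""


class SelectionError(RamanMarginError):
    """Feature selection failed or returned an empty set."""


class AssemblyError(RamanMarginError):
    """Dataset assembly violated train/validation hygiene."""


class SchemaError(RamanMarginError):
    """A file did not conform to the documented container layout."""
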