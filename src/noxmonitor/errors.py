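"""Exception hierarchy shared across the package.

The CLI maps each class to a distinct process exit code, so errors raised
deep in the pipeline surface as stable, scriptable failures.
"""


class NoxMonitorError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(NoxMonitorError):
    """Bad or missing run configuration (paths, scenario files, grids)."""

    exit_code = 2


class SpectrumValidationError(NoxMonitorError):
    """A spectrum or spectrum pair violates a structural invariant."""

    exit_code = 3


class SpectrumFormatError(SpectrumValidationError):
    """A spectrum file could not be parsed as two numeric columns."""


class WavelengthRangeError(SpectrumValidationError):
    """A wavelength request falls outside the spectrum's span."""


class NumericalError(NoxMonitorError):
    """Rank deficiency, insufficient calibration data, or failed fits."""

    exit_code = 4


class InsufficientCalibrationError(NumericalError):
    """Too few calibration spectra to fit the compensation model."""


class NotFittedError(NumericalError):
    """A model method was called before fit."""
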