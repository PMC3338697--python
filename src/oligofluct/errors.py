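"""Exception types shared across the analysis modules."""


class OligofluctError(Exception):
    """Base class for package errors."""


class InvalidDataError(OligofluctError, ValueError):
    """Input data violate a precondition (negative variance, empty ROI, ...)."""


class DegenerateFitError(OligofluctError, ValueError):
    """A fit cannot be posed (e.g. all calibration means identical)."""


class NoSignalError(OligofluctError, ValueError):
    """No fluorescence signal above noise (kappa2 <= 0 after correction)."""


class ResourceLimitError(OligofluctError, RuntimeError):
    """A request would exceed a sanity bound on problem size."""


class PrecisionError(OligofluctError, RuntimeError):
    """A numerical truncation parameter is too coarse for the requested accuracy."""


class InsufficientDataError(OligofluctError, ValueError):
    """Too few observations for the requested statistic."""


class IncompatibleCalibrationError(OligofluctError, ValueError):
    """Brightness and calibration come from different acquisition settings."""
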