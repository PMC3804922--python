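"""Exception types raised across the package."""


class EchoForceError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(EchoForceError, ValueError):
    """A numeric parameter is outside its admissible range."""


class InvalidInputError(EchoForceError, ValueError):
    """An array input has the wrong shape, dtype or contains non-finite values."""


class GeometryError(EchoForceError, ValueError):
    """An image / ROI-grid geometry is degenerate (e.g. no disc fits the mask)."""


class PhaseError(EchoForceError, ValueError):
    """An operation was applied to a timeline of the wrong phase type."""


class NormalizationError(EchoForceError, ZeroDivisionError):
    """The nRMSE normalizer (ground-truth range) is zero."""


class NumericalDegeneracyError(EchoForceError, ArithmeticError):
    """A guarded numerical identity failed (e.g. SPD rank-one denominator <= 0)."""
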