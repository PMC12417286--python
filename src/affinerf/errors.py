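"""Exception types shared across the package."""


class AffineRFError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AffineRFError, ValueError):
    """A model parameter violates its domain (non-positive scale, singular matrix, ...)."""


class UnsupportedOrderError(AffineRFError, ValueError):
    """Derivative order outside the implemented range (m <= 4)."""


class AliasingError(AffineRFError, ValueError):
    """Sine-grating frequency too high for the sampling grid."""


class DegenerateCurveError(AffineRFError, ValueError):
    """Tuning curve is identically zero (resultant undefined)."""


class DegenerateInputError(AffineRFError, ValueError):
    """Input data cannot support the requested fit or measure."""


class IncompatibleHistogramError(AffineRFError, ValueError):
    """Histograms with mismatched bin edges cannot be combined."""


class UndefinedMeasureError(AffineRFError, ValueError):
    """A local measure has no support (e.g. no neighbours within the radius)."""


class NumericalOptimizationError(AffineRFError, RuntimeError):
    """An internal numerical search failed to converge."""
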