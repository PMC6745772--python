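"""Exception hierarchy for the DENSE strain pipeline."""


class DenseStrainError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DenseStrainError, ValueError):
    """A parameter or configuration field violates its invariant."""


class GeometryError(DenseStrainError, ValueError):
    """Contours or masks violate a geometric invariant (names frame and field)."""


class FormatError(DenseStrainError, ValueError):
    """An external file could not be read or fails shape/range validation."""


class UnwrapError(DenseStrainError, RuntimeError):
    """Phase unwrapping cannot proceed (e.g. empty wall mask)."""


class TrackingError(DenseStrainError, RuntimeError):
    """Forward trajectory reconstruction failed (names the frame)."""


class DegenerateElementError(DenseStrainError, RuntimeError):
    """A quadrilateral element is singular or near-collinear."""


class ScanQualityError(DenseStrainError, RuntimeError):
    """Too few valid sectors to assemble a strain map."""


class NormalizationError(DenseStrainError, ValueError):
    """Mean strain too small to normalize (e.g. rigid motion only)."""
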