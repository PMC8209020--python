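"""Exception types shared across the pipeline."""


class FibrometryError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FibrometryError, ValueError):
    """A parameter or input violates a documented precondition."""


class UnsupportedImageError(FibrometryError, ValueError):
    """The image file or array is not a supported grayscale format."""


class InsufficientDataError(FibrometryError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedRatioError(FibrometryError, ZeroDivisionError):
    """Marker ratio requested with a non-positive denominator mean."""
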