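"""Exception hierarchy shared across the pipeline stages."""


class SpatialTimeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpatialTimeError):
    """A parameter or specification value is invalid before any work starts."""


class FormatError(SpatialTimeError):
    """An on-disk artifact is malformed or inconsistent with its companions."""


class ValidationError(SpatialTimeError):
    """An in-memory value violates a documented invariant."""


class EmptyRegionError(SpatialTimeError):
    """A region mask or polygon contains no positive area."""


class InsufficientDataError(SpatialTimeError):
    """Too few observations to run the requested computation."""


class InsufficientSignalError(SpatialTimeError):
    """An image ROI has too few pixels with usable gradient signal."""


class DegenerateInputError(SpatialTimeError):
    """Input is structurally valid but statistically degenerate."""
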