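"""Exception types raised across the pipeline."""


class ReachKinError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(ReachKinError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleConfigurationError(ReachKinError, ValueError):
    """Simulation geometry unreachable with the configured limb lengths."""


class NoMovementError(ReachKinError, ValueError):
    """Speed profile contains no movement (all zero / flat)."""


class DegenerateTrialError(ReachKinError, ValueError):
    """Segmentation threshold never crossed; trial cannot be segmented."""


class InsufficientDataError(ReachKinError, ValueError):
    """Too few frames for the requested computation."""


class InsufficientMarkersError(ReachKinError, ValueError):
    """Required marker missing in too many frames of the segment."""


class InvalidGeometryError(ReachKinError, ValueError):
    """Marker configuration is geometrically degenerate (e.g. coincident)."""


class UndefinedCorrelationError(ReachKinError, ValueError):
    """Correlation undefined (constant input vector)."""


class UndefinedEffectSizeError(ReachKinError, ValueError):
    """Effect size undefined (zero baseline standard deviation)."""


class UndefinedBandError(ReachKinError, ValueError):
    """Reference band undefined (fewer than two observations)."""


class ParseError(ReachKinError, ValueError):
    """Malformed input file."""


class SchemaError(ReachKinError, ValueError):
    """Input file misses required columns or marker labels."""
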