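"""Exception types shared across the package."""


class FidtrackError(Exception):
    """Base class for all package-specific errors."""


class DegenerateTripleError(FidtrackError, ValueError):
    """Three projection directions are (near-)coplanar: their plane
    intersection is ill-conditioned or undefined."""


class NoReferenceFoundError(FidtrackError):
    """No direction triple qualifies as a reference (every triple has a
    projection with a missing peak or peaks closer than the separation
    threshold d)."""


class AmbiguousLabelingError(FidtrackError, ValueError):
    """Marker-to-model correspondence cannot be decided because two
    pairwise distances are tied within tolerance."""


class DegenerateConfigurationError(FidtrackError, ValueError):
    """Point configuration unsuitable for a rigid fit (collinear points,
    too few correspondences)."""


class InfeasibleConfigurationError(FidtrackError, ValueError):
    """Rejection sampling cannot place the requested number of markers at
    the requested minimum separation inside the volume."""


class InvalidConfigurationError(FidtrackError, ValueError):
    """A processing parameter combination is unusable (for example the
    background window excludes every sample of a projection)."""
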