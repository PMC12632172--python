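"""Exception hierarchy shared across the package."""


class PhasemapError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleComposition(PhasemapError):
    """Requested solution flows exceed the total aqueous flow budget."""


class GridTooLarge(PhasemapError):
    """A requested Cartesian grid would exceed the configured point cap."""


class DimensionMismatch(PhasemapError):
    """Point set dimensionality does not match the design space / model."""


class UnknownMode(PhasemapError):
    """Acquisition mode or phase-model kind not recognized."""


class PointSetMismatch(PhasemapError):
    """Two posterior fields evaluated on different point sets."""


class NonGridField(PhasemapError):
    """Operation requires a posterior field on a full Cartesian grid."""


class NonPositiveSigma(PhasemapError):
    """KL divergence requested with a non-positive standard deviation."""


class DegenerateSample(PhasemapError):
    """No droplets available to compute a phase-separation fraction."""


class SingleClassInput(PhasemapError):
    """Discriminant analysis requires both PS and non-PS samples."""


class MissingIterationBudget(PhasemapError):
    """Cost model has no iteration budget configured for this dimensionality."""


class ConfigMismatch(PhasemapError):
    """Resumed campaign configuration disagrees with the persisted state."""


class CorruptState(PhasemapError):
    """Persisted campaign state cannot be parsed."""


class OverlapViolation(PhasemapError):
    """Rendered droplets overlap beyond the allowed margin."""


class OutOfFrame(PhasemapError):
    """A droplet to render does not fit inside the image frame."""


class DegenerateTrainingWarning(UserWarning):
    """Surrogate fitted on degenerate data; falling back to the prior mean."""
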