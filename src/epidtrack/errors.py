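"""Exception types shared across the package."""


class EpidTrackError(Exception):
    """Base class for package errors."""


class InvalidParameterError(EpidTrackError, ValueError):
    """A parameter or input violates a documented precondition."""


class DegenerateRegionError(EpidTrackError, ValueError):
    """A metric region is degenerate (zero mean, zero variance, flat profile)."""


class SolverFailureError(EpidTrackError, RuntimeError):
    """An iterative solver diverged."""


class FitFailureError(EpidTrackError, RuntimeError):
    """A nonlinear fit did not converge after bounded restarts."""


class NonEdgeProfileError(EpidTrackError, ValueError):
    """A profile handed to the edge fit does not look like a single edge."""


class TrackingError(EpidTrackError, RuntimeError):
    """Accuracy evaluation impossible (e.g. reference frame undetected)."""
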