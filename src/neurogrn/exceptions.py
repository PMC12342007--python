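"""Exception hierarchy shared across the package."""


class NeurognError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NeurognError, ValueError):
    """A configuration value violates its documented constraints."""


class ShapeError(NeurognError, ValueError):
    """Array dimensions are inconsistent with the declared system size."""


class CoverageError(NeurognError, ValueError):
    """A schedule or trajectory does not cover the requested time range."""


class IntegrationError(NeurognError, RuntimeError):
    """The SDE integrator produced a non-finite state.

    Attributes
    ----------
    time : float
        Simulation time (days) at which the failure was detected.
    """

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


class FitError(NeurognError, RuntimeError):
    """A network fit failed to reach the requested tolerance.

    Attributes
    ----------
    achieved : float
        Best max-abs residual reached before giving up.
    """

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


class SummaryError(NeurognError, ValueError):
    """No usable (uncensored) samples were available for a summary."""


class SchemaError(NeurognError, ValueError):
    """A serialized file does not match the expected schema version."""
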