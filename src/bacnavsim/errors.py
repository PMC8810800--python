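"""Exception hierarchy for bacnavsim.

All user-facing failure modes raise a subclass of :class:`BacnavSimError`
so callers can catch simulation failures without masking programming bugs.
"""


class BacnavSimError(Exception):
    """Base class for all bacnavsim errors."""


class InvalidInputError(BacnavSimError, ValueError):
    """An argument violates a documented precondition."""


class UnsupportedModelError(BacnavSimError, KeyError):
    """Requested cell species is not registered."""


class NoCaptureError(BacnavSimError):
    """The stimulus failed to elicit an action potential."""


class IntegrationFailureError(BacnavSimError):
    """Numerical blow-up during integration.

    Carries the first offending state variable/node and the time at which
    it was detected.
    """

    def __init__(self, message, variable=None, node=None, time_ms=None):
        super().__init__(message)
        self.variable = variable
        self.node = node
        self.time_ms = time_ms


class ConductionBlockError(BacnavSimError):
    """A velocity estimate was requested but the wave did not propagate."""


class EstimatorDegenerateError(BacnavSimError):
    """The CV estimator received degenerate input (e.g. a flat front)."""


class CalibrationError(BacnavSimError):
    """Conductance calibration is undefined or the search failed."""


class PlacementFailureError(BacnavSimError):
    """Obstacle placement could not reach the requested coverage."""


class ConfigError(BacnavSimError):
    """A configuration file failed validation.

    ``field`` names the offending key path.
    """

    def __init__(self, message, field=None):
        super().__init__(message)
        self.field = field


class SingularGeometryError(BacnavSimError):
    """Virtual electrode coincides with a source node."""


class AlignmentError(BacnavSimError):
    """Two traces do not share an overlapping time base."""
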