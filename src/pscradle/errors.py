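"""Exception hierarchy for pscradle."""


class PscradleError(Exception):
    """Base class for all pscradle errors."""


class ValidationError(PscradleError):
    """Invalid geometry, parameter, or configuration input."""


class DomainError(PscradleError):
    """Mathematical domain violation (e.g. non-positive concentration in a log)."""


class CalibrationError(PscradleError):
    """A calibration target cannot be met (e.g. would require a negative
    conductance, or a firing rate outside the achievable range)."""


class IntegrationError(PscradleError):
    """The integrator produced a non-finite state.

    Attributes
    ----------
    variable : str
        Name of the first state variable that went non-finite.
    time : float
        Simulation time (s) at which it happened.
    """

    def __init__(self, variable: str, time: float):
        self.variable = variable
        self.time = time
        super().__init__(
            f"non-finite value in state variable '{variable}' at t={time:.6g} s"
        )
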