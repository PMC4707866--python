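"""Exception hierarchy for the clot-lysis model."""


class ClotLysisError(Exception):
    """Base class for all package errors."""


class ConfigError(ClotLysisError):
    """Invalid scenario configuration (bad value, unknown key, unit mismatch)."""


class DomainError(ClotLysisError, ValueError):
    """An argument lies outside the physically admissible domain."""


class StateError(ClotLysisError):
    """A simulation state violates an invariant (negative concentration, S > theta)."""


class StabilityError(ClotLysisError):
    """An explicit time step violates its stability bound."""

    def __init__(self, message, dt=None, dt_max=None):
        super().__init__(message)
        self.dt = dt
        self.dt_max = dt_max


class IntegrationError(ClotLysisError):
    """Time integration failed; carries the last valid time reached."""

    def __init__(self, message, t_last=None):
        super().__init__(message)
        self.t_last = t_last


class ConvergenceError(ClotLysisError):
    """An iterative solver failed to converge; carries its residual history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []
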