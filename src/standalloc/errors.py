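"""Exception hierarchy shared across the package."""


class StandAllocError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(StandAllocError, ValueError):
    """An argument violates a documented precondition."""


class StabilityError(StandAllocError):
    """Explicit-Euler step would overshoot: dt * u >= 1 for some pool."""

    def __init__(self, component: str, u: float, dt: float):
        self.component = component
        self.u = u
        self.dt = dt
        super().__init__(
            f"unstable step for component '{component}': dt*u = {dt * u:.4g} >= 1 "
            f"(u = {u:.4g} yr^-1, dt = {dt:.4g} yr)"
        )


class ConfigurationError(StandAllocError):
    """A scheme or experiment configuration is incomplete or inconsistent."""


class NoGrowthError(StandAllocError):
    """No carbon is available this step, so an allocation vector is undefined."""


class SchemaError(StandAllocError):
    """A tabular input does not match the documented CSV dialect."""
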