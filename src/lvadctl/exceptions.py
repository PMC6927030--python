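"""Exception types raised across the test bench."""


class LvadCtlError(Exception):
    """Base class for all package-specific errors."""


class NoOperatingPointError(LvadCtlError):
    """The pump steady-state residual has no physical root in range."""


class IntegrationError(LvadCtlError):
    """An ODE solve failed (step rejection below the solver floor)."""


class DegenerateSignalError(LvadCtlError):
    """A detection index cannot be formed (constant derivative product)."""


class NoTransitionError(LvadCtlError):
    """No interior index extremum found; caller should keep ramping."""


class SweepRangeError(LvadCtlError):
    """A speed sweep never crossed the partial/full-support boundary."""


class VentricularCollapseError(LvadCtlError):
    """A cardiac compartment volume went negative during integration."""
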