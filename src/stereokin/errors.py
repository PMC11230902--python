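"""Exception hierarchy shared across the package."""


class StereokinError(Exception):
    """Base class for all package-specific errors."""


class UndefinedQuantityError(StereokinError, ZeroDivisionError):
    """A ratio or excess is requested for an empty pool or all-zero distribution."""


class DomainError(StereokinError, ValueError):
    """An input lies outside the mathematical domain of the operation."""


class InfeasibleObservationError(StereokinError, ValueError):
    """A (conversion, e.e.) or (d.r., d.e.) observation is inconsistent with the model.

    The message names the violated bound so the caller can report it verbatim.
    """


class SolverFailureError(StereokinError, RuntimeError):
    """The ODE integrator failed or produced unphysical (negative) amounts."""
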