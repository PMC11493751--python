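"""Exception hierarchy shared across the package."""


class AxonRveError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AxonRveError, ValueError):
    """A physical/mathematical argument is outside its admissible domain
    (nonpositive stretch, det F <= 0, a point outside a distribution's support)."""


class ParameterError(AxonRveError, ValueError):
    """An invalid parameter value or inconsistent parameter combination."""


class InputError(AxonRveError, ValueError):
    """Malformed user input (empty measurement list, mismatched grids, ...)."""


class FitError(AxonRveError, RuntimeError):
    """Distribution fitting failed or the fitted model misses its targets."""


class PackingError(AxonRveError, RuntimeError):
    """Random sequential fiber placement exhausted its attempt budget."""

    def __init__(self, message, achieved_vf=None):
        super().__init__(message)
        self.achieved_vf = achieved_vf


class MeshError(AxonRveError, RuntimeError):
    """Inconsistent mesh topology (unpaired boundary node, lost fiber node)."""


class ConvergenceError(AxonRveError, RuntimeError):
    """The quasi-static solve failed below the minimum load increment."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class OptimizationError(AxonRveError, RuntimeError):
    """The evolutionary search found no feasible candidate."""
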