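"""Exception hierarchy for model loading, compilation and simulation."""


class SbmlSimError(Exception):
    """Base class for all errors raised by this package."""


class ModelParseError(SbmlSimError):
    """The SBML document is not well-formed XML or not SBML at all."""


class ModelSemanticError(SbmlSimError):
    """The document is XML-valid but violates SBML semantics
    (unresolvable identifier, conflicting rules, bad event target, ...)."""


class UnsupportedFeatureError(SbmlSimError):
    """A construct outside the supported SBML subset was encountered."""


class CycleError(ModelSemanticError):
    """Circular dependency among initial assignments / assignment rules
    or recursive FunctionDefinitions."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("circular dependency: " + " -> ".join(self.cycle))


class SingularMatrixError(SbmlSimError):
    """LU decomposition hit a pivot below the singularity threshold."""


class ConvergenceError(SbmlSimError):
    """Newton iteration failed to reach tolerance within max_iterations."""

    def __init__(self, message, residual=None, iterations=None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class StepError(SbmlSimError):
    """An integration step produced a non-finite derivative or state."""


class NumericBlowupError(SbmlSimError):
    """State became NaN/Inf during simulation."""

    def __init__(self, variable, time):
        self.variable = variable
        self.time = time
        super().__init__(
            f"non-finite value in variable '{variable}' at t={time:g}"
        )


class EventError(SbmlSimError):
    """Event semantics violation (negative delay, livelocked cascade, ...)."""
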