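"""Exception hierarchy for popsynth."""


class PopsynthError(Exception):
    """Base class for all popsynth errors."""


class SchemaError(PopsynthError):
    """A required column or category declaration is missing or malformed."""


class ValidationError(PopsynthError):
    """Input data violates an invariant of the data model."""


class ConstraintError(PopsynthError):
    """Edge constraints or evidence contracts cannot be satisfied."""


class InfeasibleError(PopsynthError):
    """A calibration target cannot be reached from the given pool."""


class ConvergenceError(PopsynthError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
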