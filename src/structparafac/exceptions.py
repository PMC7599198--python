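"""Exception hierarchy shared across the package."""


class StructParafacError(Exception):
    """Base class for package-specific errors."""


class DimensionError(StructParafacError, ValueError):
    """Matrix or index dimensions are incompatible with the declared layout."""


class DefinitenessError(StructParafacError, ValueError):
    """A matrix required to be positive definite (or invertible) is not."""


class UnsupportedModelError(StructParafacError, ValueError):
    """The requested model configuration is outside the implemented envelope.

    Raised instead of silently returning a possibly wrong answer, e.g. for
    parameter counting under an identification/invariance combination whose
    counting convention has not been established.
    """


class ConvergenceError(StructParafacError, RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class GenerationError(StructParafacError, RuntimeError):
    """Rejection sampling of an identifiable truth exhausted its retry budget."""
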