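"""Exception types shared across the package."""


class RepliptrError(Exception):
    """Base class for package-specific errors."""


class InvalidParameterError(RepliptrError, ValueError):
    """A distribution parameter violates its admissible bound."""


class UnsupportedFamilyError(RepliptrError, ValueError):
    """An operation was requested for a family it is not defined for."""


class EmptyInputError(RepliptrError, ValueError):
    """An input carries no observations (zero total weight)."""


class DegenerateInputError(RepliptrError, ValueError):
    """Input is formally valid but carries no information for fitting."""


class NonConvergenceError(RepliptrError, RuntimeError):
    """An iterative solver hit its iteration cap before converging.

    Attributes
    ----------
    last_iterate : float
        The final iterate when the cap was reached.
    """

    def __init__(self, message: str, last_iterate: float | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


class FitFailureError(RepliptrError, RuntimeError):
    """All optimizer restarts failed to produce a usable fit."""


class ModelMisuseError(RepliptrError, ValueError):
    """The model was applied outside its validity domain (e.g. bin width too coarse)."""
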