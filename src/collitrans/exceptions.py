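"""Exception hierarchy for collitrans.

All errors raised on bad user input derive from :class:`CollitransError` so
callers (and the CLI) can catch one base class.
"""


class CollitransError(Exception):
    """Base class for all collitrans errors."""


class InvalidInputError(CollitransError, ValueError):
    """An argument is outside its physically meaningful domain."""


class InfeasibleInputError(CollitransError, ValueError):
    """A measured quantity is inconsistent with the forward model.

    Example: a total transmission larger than the ceiling the multireflection
    model permits for a perfectly transparent medium.
    """


class GridMismatchError(CollitransError, ValueError):
    """Two spectra that must share a wavelength grid do not."""


class SpectrumParseError(CollitransError, ValueError):
    """A spectrum file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConvergenceError(CollitransError, RuntimeError):
    """An iterative procedure (fit, adaptive refinement) failed to converge."""


class NoInteriorMinimumError(CollitransError, ValueError):
    """An error curve has no interior minimum (monotone perturbation model)."""
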