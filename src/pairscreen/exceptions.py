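"""Exception hierarchy.

Everything the library raises deliberately derives from :class:`PairscreenError`,
so callers (and the CLI) can distinguish domain/validation failures (exit code 1)
from genuine bugs.
"""


class PairscreenError(Exception):
    """Base class for all errors raised by pairscreen."""


class ValidationError(PairscreenError):
    """A dataset or record violates a structural invariant."""


class ParseError(PairscreenError):
    """A delimited input file could not be parsed."""


class MissingInputError(PairscreenError):
    """A prediction formula requires a measurement that is absent."""

    def __init__(self, message: str, missing: tuple[str, ...] = ()):
        super().__init__(message)
        self.missing = tuple(missing)


class DegenerateInputError(PairscreenError):
    """A formula would divide by a (near-)zero single-drug viability."""


class UnsupportedOrderError(PairscreenError):
    """A formula is not defined for the requested cocktail order."""


class DomainError(PairscreenError):
    """A mathematical operation left its domain (e.g. log of a non-positive number)."""
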