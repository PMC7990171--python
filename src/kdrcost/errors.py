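"""Exception hierarchy shared across the package."""


class KdrcostError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KdrcostError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(KdrcostError):
    """A row or record violates a data invariant (negative count, bad total, ...)."""


class DegenerateInputError(KdrcostError):
    """An operation was asked to act on input with no information (n = 0, empty schedule, ...)."""


class AmbiguousRoundingError(KdrcostError):
    """No integer genotype triple is consistent with all the printed rounded frequencies.

    Carries every candidate triple (with its mismatch score) so the caller can
    resolve the ambiguity explicitly instead of the library guessing silently.
    """

    def __init__(self, message: str, candidates: list):
        super().__init__(message)
        self.candidates = candidates


class DesignError(KdrcostError):
    """A statistical design requirement is violated (unbalanced ANOVA cell, empty cell)."""


class NoRootError(KdrcostError):
    """The Euler-Lotka equation has no finite root (net reproduction is zero)."""
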