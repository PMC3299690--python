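"""Exception hierarchy.

Every error raised by the package derives from :class:`RibophyloError`, so
pipeline callers can distinguish package failures from programming errors.
"""


class RibophyloError(Exception):
    """Base class for all package errors."""


class StructureParseError(RibophyloError):
    """Dot-bracket text could not be parsed (unbalanced brackets, ...)."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


class InputError(RibophyloError):
    """Inputs violate a precondition (length mismatch, empty list, ...)."""


class FormatError(RibophyloError):
    """A file does not follow its documented dialect."""


class AlignmentError(RibophyloError):
    """Structure and homology template columns do not agree."""


class DomainError(RibophyloError):
    """A value lies outside its mathematical domain."""


class MissingTaxonError(RibophyloError):
    """A tree leaf has no row in the character matrix."""


class AnnotationError(RibophyloError):
    """An annotation references an unknown entity id."""


class FitError(RibophyloError):
    """A regression cannot be fitted (too few points, zero variance)."""
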