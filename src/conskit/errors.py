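"""Exception hierarchy.

Every error raised by the package derives from :class:`ConskitError`, so callers
can catch one type at a pipeline boundary while still discriminating failure
modes when they need to.
"""


class ConskitError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(ConskitError):
    """Alignment rows do not all have the same length."""


class AlphabetError(ConskitError):
    """A residue outside the accepted alphabet was encountered."""


class QueryNotFoundError(ConskitError, KeyError):
    """The designated query id does not match exactly one record."""


class EmptyQueryError(ConskitError):
    """The query row contains no residues (all gaps)."""


class CompositionError(ConskitError):
    """A background composition is missing amino acids or has invalid values."""


class NoDataError(ConskitError):
    """An operation received no usable observations."""


class AmbiguousResidueError(ConskitError):
    """The wild-type residue at a position is an ambiguity code (X/B/Z)."""


class InsufficientDataError(ConskitError):
    """Too few usable points for a fit."""


class NoDecayError(ConskitError):
    """The best terminal window has a nonnegative slope (no measurable decay)."""


class NoSignalError(ConskitError):
    """A channel has zero total above-threshold signal."""


class SimSpecError(ConskitError, ValueError):
    """A simulation specification violates its own constraints."""
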