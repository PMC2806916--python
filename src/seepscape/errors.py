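"""Typed exceptions raised across the package.

Readers and model routines never silently coerce bad input; every contract
violation maps to one of these classes so callers can distinguish file-format
problems from scientific/validation problems from numerical failures.
"""


class SeepscapeError(Exception):
    """Base class for all package errors."""


class FormatError(SeepscapeError):
    """A file does not conform to the expected dialect (missing column, bad header...)."""


class ValidationError(SeepscapeError):
    """Parsed data violates a domain invariant (overlapping intervals, negative concentration...)."""


class DomainError(SeepscapeError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class NumericalError(SeepscapeError):
    """A linear system could not be solved (singular/ill-posed discretization)."""


class EstimationError(SeepscapeError):
    """An inverse problem is unidentifiable (rank-deficient layer design)."""


class AlignmentError(SeepscapeError):
    """Sequences that must be aligned are not (unequal lengths, duplicate ids)."""


class DistanceError(SeepscapeError):
    """A pairwise distance could not be computed (no comparable sites)."""


class MappingError(SeepscapeError):
    """A taxon appears in a count table but not in the group map."""


class JoinError(SeepscapeError):
    """Samples could not be joined across inputs (key mismatch)."""
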