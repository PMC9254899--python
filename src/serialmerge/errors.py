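"""Exception hierarchy for serialmerge.

All package errors derive from :class:`SerialMergeError` so callers can
catch one base class at pipeline boundaries.
"""


class SerialMergeError(Exception):
    """Base class for all serialmerge errors."""


class InvalidCellError(SerialMergeError):
    """Unit-cell parameters violate positivity / angle-range constraints."""


class InvalidMetricError(SerialMergeError):
    """A G6 vector does not describe a positive-definite metric tensor."""


class ReductionError(SerialMergeError):
    """Niggli reduction failed to converge within the step budget.

    Carries the partial result in :attr:`partial`.
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class InsufficientDataError(SerialMergeError):
    """Too few items for the requested operation (e.g. < 2 cells)."""


class HKLParseError(SerialMergeError):
    """Malformed SHELX HKL4 record; message carries the line number."""


class HKLFormatError(SerialMergeError):
    """A value does not fit the fixed-width HKL4 columns."""


class EmptySetError(SerialMergeError):
    """A reflection file or set contains no observations."""


class InvalidIndexError(SerialMergeError):
    """The (0,0,0) index, or an index outside the supported range."""


class InsufficientOverlapError(SerialMergeError):
    """Fewer than the minimum number of common unique indices for a CC."""


class UndefinedCCError(SerialMergeError):
    """Zero variance in one of the paired intensity vectors."""


class MissingAnnotationError(SerialMergeError):
    """Dendrogram operation requires an annotation that is absent."""


class MissingLabelError(SerialMergeError):
    """A dataset lacks a required truth label or cell/reflection entry."""


class ConfigError(SerialMergeError):
    """Invalid run configuration."""
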