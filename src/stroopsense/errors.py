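"""Exception hierarchy.

Every stage raises a subclass of :class:`StroopsenseError`, so orchestration
code can catch one type and report the failing stage.
"""


class StroopsenseError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(StroopsenseError):
    """A cohort specification violates its invariants."""


class InvalidParameterError(StroopsenseError):
    """A parameter is outside its documented domain."""


class InsufficientSampleError(StroopsenseError):
    """Too few observations for the requested statistical test."""


class MissingBundleError(StroopsenseError):
    """A test bundle named in the bundle map has no rows in the table."""


class DegenerateLabelsError(StroopsenseError):
    """A labelled dataset does not contain exactly two classes."""


class ClassDepletionError(StroopsenseError):
    """A filtering step would remove every member of one class."""


class AllDiscardedError(StroopsenseError):
    """A feature-selection step would retain zero features."""


class StratificationError(StroopsenseError):
    """A class is too small to appear in both partitions of a split."""


class InvalidGridError(StroopsenseError):
    """A hyperparameter grid is empty or malformed."""


class SchemaError(StroopsenseError):
    """A serialized table violates the documented schema."""


class IntegrityError(StroopsenseError):
    """A bundled fixture failed its checksum."""


class AlignmentError(StroopsenseError):
    """Two reports do not cover the same classifiers or datasets."""
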