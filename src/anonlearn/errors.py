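"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`AnonlearnError`, so callers can catch one type at a tool boundary.
"""


class AnonlearnError(Exception):
    """Base class for all package errors."""


class HierarchyFormatError(AnonlearnError):
    """A hierarchy file is malformed (ragged rows, empty file, ...)."""


class HierarchyValidationError(AnonlearnError):
    """A hierarchy violates a structural invariant (duplicate leaf,
    non-functional level mapping, coarsening violation)."""


class UnknownValueError(AnonlearnError):
    """A value has no representation in the hierarchy under the active
    unknown-value policy."""


class DomainError(AnonlearnError):
    """A numeric value falls outside an interval hierarchy's declared domain."""


class DatasetFormatError(AnonlearnError):
    """A dataset file is malformed (ragged row, unparseable numeric cell)."""


class ConfigError(AnonlearnError):
    """Inconsistent or incomplete attribute/run configuration."""


class ParameterError(AnonlearnError):
    """A privacy-model parameter is out of its admissible range."""


class InfeasibleError(AnonlearnError):
    """The requested privacy level cannot be met under the configured
    transformation options (e.g. suppression limit exceeded, no admissible
    class-size threshold, no satisfying lattice node)."""


class UndefinedMetricError(AnonlearnError):
    """A metric is undefined for the given input (empty partition,
    single-class labels, degenerate denominator)."""


class DegenerateModelError(AnonlearnError):
    """Training data contains fewer than two target classes."""
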