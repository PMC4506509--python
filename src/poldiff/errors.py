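"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`PoldiffError`, so callers (and the
CLI) can catch one type and still report which stage failed.
"""


class PoldiffError(Exception):
    """Base class for all errors raised by poldiff."""


class FormatError(PoldiffError):
    """A file does not follow the expected dialect (missing columns, bad line)."""


class ValidationError(PoldiffError):
    """Parsed content violates a data-model invariant."""


class DesignError(PoldiffError):
    """A run design is structurally invalid (pairing, conditions, replicates)."""


class NormalizationError(PoldiffError):
    """Bait normalization is impossible for at least one run."""


class ImputationError(PoldiffError):
    """The per-run noise distribution for zero imputation is undefined."""


class TestError(PoldiffError):
    """A differential test cannot be computed (too few pairs, missing counts)."""


class GridError(PoldiffError):
    """Two binned signals do not share a common bin grid."""


class EmptyClassError(PoldiffError):
    """An aggregate profile was requested for a gene class with no genes."""


class ComparisonError(PoldiffError):
    """Two profiles are not comparable (different class or layout)."""


class PlacementError(PoldiffError):
    """Synthetic genes cannot be placed under the non-overlap constraints."""


class ModelError(PoldiffError):
    """A synthetic-data model is self-inconsistent."""
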