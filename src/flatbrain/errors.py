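"""Exception hierarchy.

Every error raised by flatbrain derives from :class:`FlatbrainError`, so callers
can catch a single base class. Subclasses mirror the failure modes of the
pipeline stages: bad user input, degenerate geometry, numerical non-convergence,
and project-file validation problems.
"""


class FlatbrainError(Exception):
    """Base class for all flatbrain errors."""


class InvalidInputError(FlatbrainError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateParameterizationError(FlatbrainError):
    """Coincident consecutive points make chord-length parameters undefined."""


class DegenerateGeometryError(FlatbrainError):
    """Geometry is degenerate (collinear circle marks, zero-length tangent...)."""


class NumericalError(FlatbrainError):
    """An iterative numerical routine failed to converge."""


class ValidationError(FlatbrainError):
    """A project file or in-memory project violates its invariants."""


class DegenerateNormalizationError(FlatbrainError):
    """Signal normalization is undefined because the data are constant."""


class UndefinedCorrelationError(FlatbrainError):
    """Pearson correlation is undefined (zero variance in one input)."""


class InsufficientDataError(FlatbrainError):
    """Too few valid pixels/points for the requested statistic."""
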