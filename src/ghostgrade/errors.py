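"""Exception hierarchy shared across the pipeline stages."""


class GhostGradeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(GhostGradeError, ValueError):
    """A configuration or call parameter violates its contract."""


class OutOfBoundsError(GhostGradeError, ValueError):
    """A requested trajectory pushes image content off the canvas."""


class DegenerateInputError(GhostGradeError, ValueError):
    """Input carries no usable structure (e.g. an all-constant image)."""


class InsufficientLandmarksError(GhostGradeError, ValueError):
    """Too few vessel bifurcations to form a translation consensus."""


class InsufficientSeriesError(GhostGradeError, ValueError):
    """A longitudinal comparison needs at least two sessions."""


class UndefinedDenominatorError(GhostGradeError, ValueError):
    """An agreement percentage was requested over an empty denominator."""


class SchemaError(GhostGradeError, ValueError):
    """A CSV/JSON artifact does not match its documented schema."""


class PipelineError(GhostGradeError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
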