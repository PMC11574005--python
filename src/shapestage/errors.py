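"""Exception hierarchy shared across the package."""


class ShapeStageError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ShapeStageError, ValueError):
    """Invalid argument value (sizes, counts, levels, grids)."""


class ConfigError(ShapeStageError, ValueError):
    """Invalid atlas/cohort/pipeline configuration."""


class MeshFormatError(ShapeStageError, ValueError):
    """Malformed mesh file. Carries the 1-based header line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class GeometryError(ShapeStageError, ValueError):
    """Geometrically invalid mesh (self-intersection, degenerate faces)."""


class ValidationError(ShapeStageError, ValueError):
    """Input data failed a validation contract."""


class AlignmentError(ShapeStageError, ValueError):
    """Subject or vertex alignment mismatch between tables/matrices."""


class DesignMatrixError(ShapeStageError, ValueError):
    """Rank-deficient or otherwise unusable regression design."""


class MatchingError(ShapeStageError, ValueError):
    """Control matching cannot proceed (e.g. empty pool)."""


class LabelError(ShapeStageError, ValueError):
    """Class labels unusable for the requested classifier."""


class ImputationError(ShapeStageError, ValueError):
    """Missing-data imputation cannot be fitted."""


class SolverError(ShapeStageError, RuntimeError):
    """Iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, duality_gap: float | None = None):
        self.duality_gap = duality_gap
        if duality_gap is not None:
            message = f"{message} (duality gap {duality_gap:.3e})"
        super().__init__(message)
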