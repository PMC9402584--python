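"""Exception and warning types shared across the package."""


class PaleofinError(Exception):
    """Base class for all package errors."""


class MaskError(PaleofinError):
    """Binary mask unsuitable for outline extraction."""


class GeometryError(PaleofinError):
    """Degenerate or invalid polygon geometry."""


class ConversionError(PaleofinError):
    """Body-length conversion produced a non-physical value."""


class DesignError(PaleofinError):
    """Rank-deficient or otherwise unusable regression design."""


class SingularCovarianceError(PaleofinError):
    """Phylogenetic covariance matrix is not positive definite."""


class PredictionError(PaleofinError):
    """New observation incompatible with a fitted model."""


class IdentifiabilityError(PaleofinError):
    """Model parameters not identifiable on the given tree."""


class CladeError(PaleofinError):
    """Requested clade cannot be located in any tree."""


class ConvergenceError(PaleofinError):
    """Iterative procedure failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class ParseError(PaleofinError):
    """Malformed input file."""


class InputError(PaleofinError):
    """Invalid input data."""


class ConfigError(PaleofinError):
    """Invalid or incomplete pipeline configuration."""


class PipelineError(PaleofinError):
    """Failure inside a pipeline stage, tagged with the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class GeometryWarning(UserWarning):
    """Suspicious but non-fatal geometry (e.g. self-intersecting polygon)."""
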