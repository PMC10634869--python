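"""Exception hierarchy shared across the package."""


class MidzoneError(Exception):
    """Base class for all package-specific errors."""


class SpatialGraphParseError(MidzoneError):
    """Malformed Amira SpatialGraph or CSV network file."""


class UnsupportedDialectError(SpatialGraphParseError):
    """Binary or otherwise unsupported SpatialGraph dialect."""


class InvariantError(MidzoneError, ValueError):
    """A domain-type invariant was violated."""


class UndefinedAngleError(MidzoneError):
    """End-to-end vector of a filament is zero (closed loop)."""


class NoDipError(MidzoneError):
    """Profile has no interior dip so an overlap width is undefined."""


class EdgeTruncationError(MidzoneError):
    """Profile peak sits on the domain edge; width would be truncated."""


class EmptyMaskError(MidzoneError):
    """Embryo segmentation found no foreground."""


class DetectionError(MidzoneError):
    """Pole/chromatid detection failed in a way that cannot be flagged per frame."""


class FitError(MidzoneError):
    """A model fit did not converge."""


class ConfigError(MidzoneError):
    """Invalid pipeline configuration."""


class MissingInputError(MidzoneError):
    """A required input file does not exist."""


class StageError(MidzoneError):
    """A pipeline stage failed."""
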