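"""Exception hierarchy for laserline."""


class LaserlineError(Exception):
    """Base class for all laserline errors."""


class DegenerateGeometryError(LaserlineError, ValueError):
    """A measurement set admits no well-defined estimate (e.g. the
    vanishing point is undefined, or the projected laser lines are
    parallel in the image)."""


class VanishingPointAtInfinity(DegenerateGeometryError):
    """The two annotated laser lines are parallel in the image: the
    vanishing point is at infinity and the camera is effectively
    horizontal with zero pan.  Callers may fall back to the
    zero-pose (simple-case) estimators."""


class AnnotationError(LaserlineError, ValueError):
    """An annotation set is inconsistent (rows swapped, lines diverging
    toward the horizon, malformed file, ...)."""


class DetectionError(LaserlineError, RuntimeError):
    """Laser-line extraction from a raster image failed."""


class ConfigError(LaserlineError, ValueError):
    """A configuration file is missing a key or holds an invalid value."""
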