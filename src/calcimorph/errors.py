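"""Exception hierarchy for calcimorph.

Every error raised by the package derives from :class:`CalcimorphError`
so callers can catch domain failures without masking programming errors.
"""


class CalcimorphError(Exception):
    """Base class for all calcimorph domain errors."""


class GridMismatchError(CalcimorphError):
    """Two grids that must share shape/spacing/origin do not."""


class GeometryError(CalcimorphError):
    """Phantom geometry cannot be realized on the requested grid."""


class ConfigurationError(CalcimorphError):
    """Invalid cohort or pipeline configuration."""


class IntegrityError(CalcimorphError):
    """A label map or table violates its structural invariants."""


class CollinearityError(CalcimorphError):
    """A regression design is rank-deficient."""


class DegenerateDataError(CalcimorphError):
    """Data too degenerate for the requested statistic (constant input, etc.)."""


class GroupSizeError(CalcimorphError):
    """A comparison stratum has too few members."""


class DependencyError(CalcimorphError):
    """A pipeline stage is missing an upstream artifact."""


class DimensionalityError(CalcimorphError):
    """A volume file does not contain a single 3D scalar grid."""
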