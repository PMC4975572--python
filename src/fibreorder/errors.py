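"""Exception and warning types shared across the pipeline."""


class FibreOrderError(Exception):
    """Base class for all fibreorder errors."""


class InsufficientDataError(FibreOrderError, ValueError):
    """Too few points for the requested computation (e.g. < 4 nuclei for a fit)."""


class DegenerateGeometryError(FibreOrderError, ValueError):
    """Fitted geometry is unusable, e.g. near-collinear nuclei give a radius below the floor."""


class UndefinedAzimuthError(FibreOrderError, ValueError):
    """A nucleus lies on the cylinder axis, so its azimuth is undefined."""


class DegenerateNormalizationError(FibreOrderError, ValueError):
    """MO ≈ MR: the orderness score denominator is numerically zero."""


class UndefinedStatisticError(FibreOrderError, ValueError):
    """A requested statistic does not exist (e.g. ANOVA F with zero within-group variance)."""


class ParseError(FibreOrderError, ValueError):
    """A coordinate file violates the expected layout; the message names line numbers."""


class PipelineError(FibreOrderError, RuntimeError):
    """A whole pipeline run failed (every fibre errored)."""


class DuplicatePointsWarning(UserWarning):
    """Two nuclei share identical surface coordinates (nearest-neighbour distance 0)."""


class LatticeFallbackWarning(UserWarning):
    """The requested point count admits no evenly divided row layout; nearest row count used."""
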