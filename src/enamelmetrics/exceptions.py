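"""Exception hierarchy for enamelmetrics."""


class EnamelMetricsError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(EnamelMetricsError):
    """Input file or stream cannot be parsed into valid data."""


class FormatError(EnamelMetricsError):
    """File violates its declared dialect (e.g. mixed delimiters)."""


class IntegrityError(EnamelMetricsError):
    """Measurement table violates a uniqueness/consistency constraint."""


class ParameterError(EnamelMetricsError):
    """A numeric parameter is outside its valid range."""


class DegenerateGeometryError(EnamelMetricsError):
    """Point configuration does not support the requested fit/triangulation."""


class GeometryError(EnamelMetricsError):
    """Transect or offset geometry leaves the surface extent."""


class UnusableTransectError(EnamelMetricsError):
    """Too many transect samples fall on unmeasured cells."""


class NoDefectFoundError(EnamelMetricsError):
    """No groove minimum survives amplitude thresholding on the profile."""


class PairingError(EnamelMetricsError):
    """Feature ids cannot be matched one-to-one across two measurement sets."""


class MissingReferenceError(EnamelMetricsError):
    """No perikymata reference pool exists for a defect at any fallback level."""


class ModelError(EnamelMetricsError):
    """A statistical model cannot be estimated from the given records."""


class AggregationError(EnamelMetricsError):
    """Replicate aggregation called on an empty or inconsistent set."""


class SpecError(EnamelMetricsError):
    """A synthetic-surface or cohort specification is invalid."""
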