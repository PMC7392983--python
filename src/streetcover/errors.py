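"""Exception hierarchy shared across the pipeline stages."""


class StreetcoverError(Exception):
    """Base class for all package errors."""


class InvalidInputError(StreetcoverError):
    """Malformed or empty geometry / table input."""


class ProjectionExtentError(InvalidInputError):
    """Geometry spans too large an area for a planar city projection."""


class DegenerateSpreadError(StreetcoverError):
    """A vector with zero spread cannot be Z-scored."""


class OverlappingUnitsError(StreetcoverError):
    """Subcity unit interiors overlap; assignment would be ambiguous."""


class UndefinedUnitError(StreetcoverError):
    """A coverage summary was requested for an empty unit."""


class SeparationError(StreetcoverError):
    """Outcome is degenerate (all 0 or all 1); logistic fit is not identified."""


class RankDeficiencyError(StreetcoverError):
    """Fewer rows than fixed-effect parameters."""


class StageDependencyError(StreetcoverError):
    """A pipeline stage was invoked before its upstream artifact exists."""


class DegenerateConfigError(StreetcoverError):
    """A synthetic-city configuration yields no roads or no candidate sites."""
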