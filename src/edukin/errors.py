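"""Exception hierarchy.

All domain errors derive from :class:`EdukinError` so callers can catch one
base class; parameter-domain problems additionally derive from ``ValueError``
to behave naturally in numeric code.
"""


class EdukinError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EdukinError, ValueError):
    """A kinetic or protocol parameter is outside its valid domain."""


class InsufficientDataError(EdukinError, ValueError):
    """Too few data points to attempt the requested estimate."""


class EmptyPopulationError(EdukinError, ValueError):
    """An operation requires at least one cell."""


class PlacementError(EdukinError, RuntimeError):
    """Rejection sampling could not place the requested nuclei at the
    requested minimum separation within the placement budget."""


class ConfigError(EdukinError, ValueError):
    """A run configuration is malformed (unknown key, missing block...)."""


class TableFormatError(EdukinError, ValueError):
    """A delimited input table does not match the expected schema."""
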