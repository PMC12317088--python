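"""Exception hierarchy for poolreg.

All library errors derive from :class:`PoolregError` so callers (and the CLI)
can distinguish pipeline failures from programming errors.
"""


class PoolregError(Exception):
    """Base class for all poolreg errors."""


class ValidationError(PoolregError, ValueError):
    """An input violated a documented precondition."""


class ConfigurationError(PoolregError, ValueError):
    """An unknown method identifier or inconsistent configuration."""


class InsufficientMatchesError(PoolregError):
    """Too few match candidates to attempt robust geometric filtering."""


class DegenerateGeometryError(PoolregError):
    """The matched point configuration does not determine a transform."""
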