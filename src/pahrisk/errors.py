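"""Exception hierarchy shared across the package."""


class PahriskError(ValueError):
    """Base class for all pahrisk errors."""


class SchemaError(PahriskError):
    """An input table is missing a required column or has a malformed layout."""


class ValidationError(PahriskError):
    """A value violates a domain invariant (negative concentration, zero factor, ...)."""


class RouteError(PahriskError):
    """An operation was applied to a scenario of the wrong exposure route."""


class ConfigError(PahriskError):
    """A simulation or pipeline configuration is inconsistent."""
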