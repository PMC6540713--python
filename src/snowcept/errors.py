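"""Exception hierarchy shared across the package."""


class SnowceptError(Exception):
    """Base class for all package-specific errors."""


class InputError(SnowceptError, ValueError):
    """A value or container violates a documented precondition."""


class SchemaError(SnowceptError, ValueError):
    """A CSV/config file does not match its declared schema."""


class FitError(SnowceptError, ValueError):
    """A model or regression fit cannot be carried out on the given data."""
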