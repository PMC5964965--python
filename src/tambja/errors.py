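"""Exception types shared across the package."""


class TambjaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TambjaError, ValueError):
    """A CSV or table does not conform to the expected schema."""


class InputError(TambjaError, ValueError):
    """Inputs violate an operation's preconditions."""


class FitError(TambjaError, RuntimeError):
    """A model fit failed to converge or the design is degenerate."""
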