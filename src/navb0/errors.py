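"""Exception types shared across the package."""


class SchemaError(KeyError):
    """Raised when an on-disk container is missing a required group or attribute."""


class ValidationError(ValueError):
    """Raised when in-memory objects violate a structural invariant."""
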