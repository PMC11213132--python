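"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class SchemaError(ValueError):
    """A tabular or JSON input is missing mandatory structure."""


class ValidationError(ValueError):
    """A record carries a value outside its documented bounds."""
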