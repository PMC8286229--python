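"""Exception hierarchy shared across the pipeline."""


class ValidationError(ValueError):
    """An in-memory object or loaded file violates a declared invariant."""


class FormatError(ValidationError):
    """An on-disk file does not have the expected layout (columns, shape)."""


class ParameterError(ValueError):
    """A parameter combination is outside the valid domain."""
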