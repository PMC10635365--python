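class ValidationError(ValueError):
    """An input violates one of the documented contracts."""


class LeakageError(RuntimeError):
    """An augmented training instance traces to a validation-fold parent."""
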