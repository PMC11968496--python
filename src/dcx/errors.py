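"""Exception types shared across the pipeline stages."""


class ParameterError(ValueError):
    """A stage was called with an invalid parameter (bad threshold, size, seed...)."""


class ValidationError(ValueError):
    """An input table or matrix violates its contract (e.g. non-positive fold change)."""
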