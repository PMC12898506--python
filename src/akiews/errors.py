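"""Shared exception types."""


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class InputError(ValueError):
    """Malformed input data (unsorted series, negative volumes, ...)."""
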