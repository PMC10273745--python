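"""Exception types used across the package."""


class ConfigurationError(ValueError):
    """Bad configuration: missing columns, mismatched genome builds, malformed intervals."""


class InputError(ValueError):
    """Unusable input data, e.g. an empty summary-statistics file."""


class PipelineError(RuntimeError):
    """Internal inconsistency detected while orchestrating an analysis."""
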