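"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Raised when a config object or config file is internally inconsistent."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot produce a usable result
    (e.g. every subject excluded, insufficient trials for a split)."""
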