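"""Exception types shared across the package."""


class FlmetaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FlmetaError, ValueError):
    """An invalid configuration field; the message names the field."""


class ScaleError(FlmetaError, ValueError):
    """An operation was applied to data on the wrong scale (linear vs log2)."""


class PipelineError(FlmetaError, RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
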