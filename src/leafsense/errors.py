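"""Exception types shared across the pipeline."""


class LeafSenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LeafSenseError, ValueError):
    """Invalid configuration or parameter value."""


class ShapeMismatchError(LeafSenseError, ValueError):
    """Two rasters that must share a shape do not."""


class EmptyMaskError(LeafSenseError, ValueError):
    """An operation that needs foreground pixels received an empty mask."""


class VocabularyError(LeafSenseError, ValueError):
    """A visual vocabulary could not be built or does not match its input."""


class PipelineError(LeafSenseError, RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
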