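"""Exception hierarchy shared across the pipeline stages."""


class H1BlocksError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(H1BlocksError, ValueError):
    """Input data violates an invariant (coordinates, counts, categories)."""


class AlignmentError(H1BlocksError, ValueError):
    """An interval does not align to the declared window grid."""


class SizingError(H1BlocksError, ValueError):
    """A simulated genome is too small for the requested content."""


class ConfigurationError(H1BlocksError, ValueError):
    """A parameter combination is inconsistent or out of range."""


class PipelineError(H1BlocksError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
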