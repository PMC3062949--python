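"""Exception hierarchy for tubeness."""


class TubenessError(Exception):
    """Base class for all tubeness errors."""


class InvalidParameterError(TubenessError, ValueError):
    """A filter or generator parameter is outside its valid domain."""


class InvalidInputError(TubenessError, ValueError):
    """An input volume or field violates a precondition (shape, finiteness)."""


class DegenerateInputError(TubenessError, ValueError):
    """The input admits no meaningful answer (e.g. constant volume for auto-c)."""


class VolumeFormatError(TubenessError, IOError):
    """A volume file cannot be read or written in the requested format."""


class PipelineError(TubenessError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
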