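"""Exception hierarchy shared across the pipeline."""


class CraniorecError(Exception):
    """Base class for all package errors."""


class InputError(CraniorecError, ValueError):
    """Caller supplied invalid data (empty mask, bad parameter, ...)."""


class FormatError(CraniorecError, ValueError):
    """A file on disk does not satisfy the expected format contract."""


class ConfigError(CraniorecError, ValueError):
    """A configuration object violates its schema or invariants."""


class PipelineError(CraniorecError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
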