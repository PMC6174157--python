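"""Exception hierarchy shared by all pipeline stages."""


class MirtfnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MirtfnetError, ValueError):
    """A configuration value is missing or outside its documented domain."""


class InputError(MirtfnetError, ValueError):
    """User-supplied data violates a documented precondition."""


class GenerationError(MirtfnetError, RuntimeError):
    """The synthetic cohort cannot satisfy the requested constraints."""
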