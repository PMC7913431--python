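"""Exception hierarchy shared across the pipeline stages."""


class ExonetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ExonetError):
    """A simulation or run configuration is internally inconsistent."""


class InputError(ExonetError):
    """Input data violate a precondition (wrong shape, missing group, ...)."""


class FormatError(ExonetError):
    """A table is missing required columns or carries unknown labels."""
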