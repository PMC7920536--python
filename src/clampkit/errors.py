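"""Package exception hierarchy."""


class ClampkitError(Exception):
    """Base class for package errors."""


class FitError(ClampkitError):
    """A curve fit failed to converge or the data violate the model."""


class InsufficientEventsError(ClampkitError):
    """Too few candidate events to build a template or average."""


class ConfigError(ClampkitError):
    """Invalid run configuration."""
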