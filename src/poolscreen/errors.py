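"""Exception types shared across the package."""


class PoolscreenError(Exception):
    """Base class for package errors."""


class ConfigurationError(PoolscreenError):
    """A design, catalog, or parameter set is internally inconsistent."""


class MalformedReadError(PoolscreenError):
    """A read is too short (or otherwise unusable) for the fixed layout.

    Quantification counts these instead of aborting; the scalar helpers
    raise so that callers can decide.
    """
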