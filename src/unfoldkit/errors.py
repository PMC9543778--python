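"""Exception hierarchy shared across the pipeline stages."""


class UnfoldkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(UnfoldkitError, ValueError):
    """Invalid configuration value or unknown configuration key."""


class InsufficientDataError(UnfoldkitError, ValueError):
    """Too few samples/events to perform the requested estimate."""


class FitError(UnfoldkitError, RuntimeError):
    """A least-squares fit failed to converge or is degenerate."""


class CorrectionError(UnfoldkitError, RuntimeError):
    """A raw curve could not be baseline/contact corrected."""


class FormatError(UnfoldkitError, ValueError):
    """A curve file or manifest violates the on-disk format."""


class PipelineError(UnfoldkitError, RuntimeError):
    """A whole-pipeline failure (e.g. no usable events at the end)."""
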