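"""Exception types shared across the package."""


class TnzSizeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TnzSizeError, ValueError):
    """A configuration value violates its invariants."""


class GenerationError(TnzSizeError, RuntimeError):
    """The synthetic generator cannot produce valid data under this configuration."""


class TraceTooShortError(TnzSizeError, ValueError):
    """A respirometry trace has fewer readings than the extraction window."""


class NoTNZError(TnzSizeError, RuntimeError):
    """The fitted metabolic curve has no interior minimum, so no TNZ exists."""


class DataError(TnzSizeError, ValueError):
    """Input data violate a modelling precondition (non-positive response, empty join, ...)."""


class FitError(TnzSizeError, RuntimeError):
    """A model fit is impossible (rank deficiency, too few groups, ...)."""
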