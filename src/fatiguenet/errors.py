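"""Exception hierarchy shared across the pipeline."""


class FatigueNetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FatigueNetError, ValueError):
    """Invalid parameter values detected before any computation runs."""


class GeometryError(FatigueNetError, ValueError):
    """Array shapes incompatible with the requested operation."""


class DegenerateInputError(FatigueNetError, ValueError):
    """Input is structurally valid but carries no usable information
    (all-zero eigenvalues, single-class labels, ...)."""


class FormatError(FatigueNetError, ValueError):
    """A file could not be parsed as the expected on-disk format."""
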