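"""Exception types raised across the package."""


class MSIError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MSIError, ValueError):
    """A file or spectrum violates the expected format."""


class DimensionError(MSIError, ValueError):
    """Inputs have inconsistent shapes or sizes."""


class UniquenessError(MSIError, ValueError):
    """Duplicate (sample, i, j) pixel locations."""


class ParameterError(MSIError, ValueError):
    """An argument is outside its valid range."""
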