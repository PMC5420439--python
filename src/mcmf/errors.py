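"""Exception types shared across the package."""


class McmfError(Exception):
    """Base class for package-specific errors."""


class FormatError(McmfError):
    """Input raster has an unsupported layout (wrong channel count, dtype...)."""


class DegenerateInputError(McmfError):
    """Input is structurally valid but carries no usable signal."""


class ParameterError(McmfError, ValueError):
    """A configuration value is outside its documented range."""
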