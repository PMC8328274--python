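"""Exception hierarchy shared across the pipeline."""


class PlexusCountError(Exception):
    """Base class for all errors raised by plexuscount."""


class ParameterError(PlexusCountError, ValueError):
    """A user-supplied parameter is outside its valid domain."""


class UnsupportedImageError(PlexusCountError):
    """The input raster is not a 2-D single- or three-channel image."""


class DegenerateInputError(PlexusCountError):
    """The input carries no usable signal (e.g. a constant threshold region)."""


class ConsistencyError(PlexusCountError):
    """Two inputs that must describe the same image disagree."""


class FitError(PlexusCountError):
    """A model fit cannot be performed on the given data."""


class CapacityError(PlexusCountError):
    """A synthetic layout cannot be placed within the requested canvas."""
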