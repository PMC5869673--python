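"""Exception hierarchy.

All concrete errors subclass :class:`ValueError` so callers that do not care
about the distinction can catch the built-in type.
"""


class MozzageError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(MozzageError):
    """A spectral table file does not conform to the expected dialect."""


class GridError(MozzageError):
    """Wavelength grid is malformed, or an interval does not intersect it."""


class MetadataError(MozzageError):
    """A required per-mosquito metadata field is missing or invalid."""


class MissingDataError(MozzageError):
    """Rows contain missing absorbance values."""


class ConfigurationError(MozzageError):
    """Invalid combination of user-supplied options."""


class DegenerateInputError(MozzageError):
    """Input carries no usable signal (e.g. all-constant spectra)."""


class SizeError(MozzageError):
    """A dataset or partition is too small for the requested operation."""
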