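"""Exception hierarchy for the suitability-mapping pipeline."""


class SuitmapError(Exception):
    """Base class for all package errors."""


class ValidationError(SuitmapError, ValueError):
    """A parameter or input violates a documented precondition."""


class FormatError(SuitmapError, ValueError):
    """A file is not in the expected on-disk format."""


class GridMismatchError(ValidationError):
    """Two rasters that must share a grid do not."""
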