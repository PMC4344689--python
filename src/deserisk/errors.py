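"""Exception hierarchy for the deserisk package."""


class DeseriskError(Exception):
    """Base class for all package errors."""


class GridFormatError(DeseriskError):
    """A raster file does not follow the ESRI ASCII grid dialect."""


class ValidationError(DeseriskError):
    """An input violates a documented precondition or invariant."""


class DegenerateInputError(DeseriskError):
    """An input is too degenerate for the operation (constant layer, zero variance...)."""
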