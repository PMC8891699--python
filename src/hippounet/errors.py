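"""Exception types shared across the package."""


class HippoUnetError(Exception):
    """Base class for package errors."""


class FormatError(HippoUnetError):
    """A file or array does not satisfy the expected on-disk format."""


class DegenerateInputError(HippoUnetError):
    """Input is structurally valid but degenerate (e.g. constant volume, empty mask)."""


class SpecError(HippoUnetError):
    """A generative or run specification is internally inconsistent."""


class ShapeError(HippoUnetError):
    """Array shapes are incompatible with the requested operation."""
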