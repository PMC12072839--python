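"""Exception hierarchy shared across the package."""


class MicrodamageError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MicrodamageError, ValueError):
    """A supplied parameter is out of its valid range or inconsistent."""


class SizingError(ParameterError):
    """The phantom body does not fit inside the requested image."""


class ManifestError(MicrodamageError, ValueError):
    """A stack manifest is malformed (duplicate indices, bad fields)."""


class FormatError(MicrodamageError, ValueError):
    """An image file has an unsupported format or bit depth."""


class SegmentationError(MicrodamageError, RuntimeError):
    """Segmentation could not find an object in the slice."""


class EmptyDomainError(MicrodamageError, ValueError):
    """An operation requires a non-empty object region but found none."""


class DegenerateMaskError(MicrodamageError, RuntimeError):
    """Rejection sampling exceeded its proposal budget on a near-empty mask."""
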