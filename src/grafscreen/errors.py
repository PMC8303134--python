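"""Exception hierarchy used across the package."""


class GrafScreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GrafScreenError, ValueError):
    """A value violates a documented invariant; the message names the bound."""


class DegenerateLineError(ValidationError):
    """Two coincident points cannot define a line."""


class MissingLandmarkError(GrafScreenError):
    """A structure mask is empty, so its landmark cannot be extracted."""


class AnnotationParseError(GrafScreenError, ValueError):
    """An annotation document uses an unknown label or malformed geometry."""


class DicomConversionError(GrafScreenError):
    """The DICOM file cannot be converted (e.g. no pixel data)."""
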