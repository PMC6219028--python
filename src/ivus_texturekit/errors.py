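"""Exception hierarchy used across the toolkit.

Every contract violation raises a subclass of :class:`TextureKitError` so
callers can catch toolkit failures without swallowing programming errors.
"""


class TextureKitError(Exception):
    """Base class for all toolkit errors."""


class DimensionError(TextureKitError):
    """Arrays that must share a shape do not."""


class FormatError(TextureKitError):
    """An image file is not single-channel 8-bit grayscale."""


class LabelPaletteError(TextureKitError):
    """A mask/label image contains values outside the documented palette."""


class ParameterError(TextureKitError):
    """An operation received an invalid parameter (even window, k > 54, ...)."""


class BoundsError(TextureKitError):
    """A window center falls outside its frame."""


class SchemaError(TextureKitError):
    """A feature table is missing canonical columns or names unknown ones."""


class DegenerateInputError(TextureKitError):
    """Input carries no usable signal (empty mask, all-constant matrix, ...)."""


class ClassCoverageError(TextureKitError):
    """A classifier's training pool lacks one of its two classes."""


class UndefinedRateError(TextureKitError):
    """A rate or ROC curve is undefined (empty positive or negative class)."""
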