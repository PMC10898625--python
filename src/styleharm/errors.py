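"""Exception taxonomy shared across the package."""


class StyleharmError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(StyleharmError, ValueError):
    """A precondition on user-supplied arguments was violated."""


class ConfigError(StyleharmError, ValueError):
    """Inconsistent model or training configuration."""


class ShapeError(StyleharmError, ValueError):
    """An array does not have the shape a network or loss expects."""


class DataError(StyleharmError, ValueError):
    """Non-finite or otherwise unusable image data."""


class VolumeIOError(StyleharmError, IOError):
    """A volume file could not be read or written."""


class DimensionError(StyleharmError, ValueError):
    """An image file does not have exactly three spatial axes."""


class AssemblyError(StyleharmError, ValueError):
    """Slice bookkeeping is inconsistent during volume reassembly."""


class ModelError(StyleharmError, RuntimeError):
    """The model is unusable (e.g. non-finite parameters)."""


class TrainingDivergenceError(StyleharmError, RuntimeError):
    """A loss term became non-finite during training."""


class SegmentationDegenerateError(StyleharmError, ValueError):
    """The image has no intensity structure to segment."""
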