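"""Exception hierarchy for the detection pipeline."""


class MasscadError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MasscadError):
    """An input file decodes but is not in an accepted format."""


class AnnotationError(MasscadError):
    """A ground-truth annotation fails validation against its image."""


class ConfigError(MasscadError):
    """A configuration value is outside its documented range."""


class EmptyBreastError(MasscadError):
    """Breast segmentation found no foreground pixels."""


class ParameterError(MasscadError):
    """An operation parameter is outside its valid range."""


class DegenerateShapeError(MasscadError):
    """Too few or collinear boundary points for an ellipse fit."""


class PlacementError(MasscadError):
    """Phantom object placement failed after repeated rejection sampling."""


class TrainingError(MasscadError):
    """Classifier training is impossible on the provided labels."""
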