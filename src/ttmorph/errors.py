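"""Exception hierarchy for ttmorph."""


class TTMorphError(Exception):
    """Base class for all ttmorph errors."""


class VolumeFormatError(TTMorphError, ValueError):
    """Raised when a file is not a readable integer label volume."""


class ConfigurationError(TTMorphError, ValueError):
    """Raised when label roles overlap or a run configuration is invalid."""


class BoundsError(TTMorphError, IndexError):
    """Raised when a crop window or slice index lies outside the volume."""


class MeasurementError(TTMorphError, ValueError):
    """Raised when a morphometric quantity is undefined for the input."""


class SceneSpecificationError(TTMorphError, ValueError):
    """Raised when a synthetic scene specification is geometrically impossible."""


class DegenerateDataError(TTMorphError, ValueError):
    """Raised when a statistical routine receives degenerate input (e.g. constant data)."""
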