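"""Exception hierarchy for screening-pipeline failures.

Every error names the entity (plate, well, label, parameter) it refers to so
that a failed stage in a multi-plate run is traceable from the message alone.
"""


class HcscreenError(Exception):
    """Base class for all package errors."""


class ParameterError(HcscreenError, ValueError):
    """An invalid parameter value (non-positive width, bad volume, ...)."""


class PlacementError(HcscreenError):
    """Simulated cells cannot be placed without overlap on the given field."""


class SegmentationError(HcscreenError):
    """Thresholding or labeling produced an unusable result."""


class LabelingError(HcscreenError):
    """Nucleus/cell label sets are inconsistent."""


class LayoutError(HcscreenError):
    """A plate layout violates its invariants (missing control roles, ...)."""


class NormalizationError(HcscreenError):
    """Plate normalization cannot be anchored (bad control medians)."""


class ConfigError(HcscreenError):
    """A run configuration contains unknown keys or invalid values."""
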