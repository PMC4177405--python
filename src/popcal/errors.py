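"""Exception types shared across the pipeline."""


class PopcalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PopcalError):
    """Invalid protocol, scene, or run configuration."""


class ShapeError(PopcalError):
    """Array arguments whose shapes are inconsistent."""


class InvalidRoiError(PopcalError):
    """ROI with an empty mask or outside image bounds."""


class DegenerateNeuropilError(PopcalError):
    """Neuropil region fully covered by somata for a cell."""


class DegenerateDataError(PopcalError):
    """Statistic requested on data with no usable variation."""


class PlacementError(PopcalError):
    """Could not place the requested number of somata without overlap."""


class NormalizationError(PopcalError):
    """Brightness normalization impossible (e.g. no beads detected)."""


class FormatError(PopcalError):
    """Malformed or schema-violating input file."""
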