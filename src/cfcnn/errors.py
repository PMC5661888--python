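"""Exception types shared across the package.

All derive from ValueError so callers can catch broadly; the subclasses let
tests and pipelines distinguish geometry problems (bad boxes, shape
mismatches) from configuration and degenerate-input problems.
"""


class GeometryError(ValueError):
    """A coordinate, box, or array shape is inconsistent with the volume."""


class DimensionalityError(GeometryError):
    """Input data does not have the expected number of dimensions."""


class ConfigError(ValueError):
    """An experiment or model configuration is invalid or incomplete."""


class DomainError(ValueError):
    """A scalar argument lies outside its mathematical domain."""


class DegenerateClassError(ValueError):
    """A weighting region contains only one voxel class."""


class UndefinedMetricError(ValueError):
    """A metric's denominator set is empty, so the value is undefined."""


class SegmentationStartError(ValueError):
    """The starting slice produced no nodule voxels; propagation cannot begin."""
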