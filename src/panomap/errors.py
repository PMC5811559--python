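"""Exception hierarchy for the panoramic mapping pipeline."""


class PanomapError(Exception):
    """Base class for all panomap errors."""


class UnprojectablePointError(PanomapError):
    """A world point lies at or behind the camera plane (Z <= 0)."""


class CalibrationError(PanomapError):
    """Calibration could not be performed (underdetermined or degenerate)."""


class LabelingError(PanomapError):
    """Grid-junction labeling failed (inconsistent anchors or topology)."""


class SegmentationError(PanomapError):
    """Silhouette segmentation produced an empty or invalid mask."""


class StackError(PanomapError):
    """Silhouette stack construction failed (inconsistent shapes/angles)."""


class CarvingError(PanomapError):
    """Visual-hull carving received degenerate input."""


class MeshError(PanomapError):
    """Surface extraction or mesh processing failed."""


class SignalError(PanomapError):
    """Signal conditioning contract violation (e.g. Nyquist, empty mask)."""


class ProjectionError(PanomapError):
    """Surface projection failure (length mismatch, uncalibrated camera)."""


class ConfigError(PanomapError):
    """Pipeline configuration failed validation."""
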