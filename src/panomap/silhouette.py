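"""Binary silhouette segmentation and the rotation silhouette stack.

The epicardial geometry is recovered from images of the hanging heart
taken by a single calibrated camera while a motorized stage rotates the
heart through 360 degrees (one image every 5 degrees in the standard
protocol).  Each image is reduced to a binary silhouette — heart pixels
one, background zero — by thresholding plus optional polygon edits, and
the per-angle masks are collected into a :class:`SilhouetteStack` that
the visual-hull carver consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .camera_geometry import CameraModel
from .errors import SegmentationError, StackError

__all__ = ["SilhouetteStack", "segment_silhouette", "assemble_stack"]


@dataclass
class SilhouetteStack:
    """Ordered binary silhouettes with their stage rotation angles.

    ``masks`` is (n_angles, H, W) with heart pixels 1; ``angles`` are the
    stage angles in degrees, strictly increasing and spanning less than a
    full turn.  ``camera`` is the geometry camera; ``rotation_axis`` is a
    unit world vector and ``axis_point`` a point on the axis (the cannula
    is assumed to pass through the calibrated world origin by default).
    """

    masks: np.ndarray
    angles: np.ndarray
    camera: CameraModel
    rotation_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.masks.ndim != 3:
            raise StackError("masks must be a (n_angles, H, W) array")
        if len(self.masks) != len(self.angles):
            raise StackError("one angle required per mask")
        if len(self.angles) > 1:
            if np.any(np.diff(self.angles) <= 0):
                raise StackError("angles must be strictly increasing")
            if self.angles[-1] - self.angles[0] >= 360.0:
                raise StackError("angles must span less than 360 degrees")
        if not np.isin(self.masks, (0, 1)).all():
            raise StackError("masks must be binary (0/1)")
        self.masks = self.masks.astype(np.uint8)
        self.rotation_axis = np.asarray(self.rotation_axis, dtype=float)
        self.rotation_axis = self.rotation_axis / np.linalg.norm(self.rotation_axis)
        self.axis_point = np.asarray(self.axis_point, dtype=float)

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks.shape[1:]


def segment_silhouette(
    image: np.ndarray,
    threshold: float | None = None,
    polygon_edits: list[tuple[np.ndarray, str]] | None = None,
    *,
    dark_object: bool = True,
    fill_holes: bool = True,
    keep_largest: bool = True,
) -> np.ndarray:
    """Segment the heart silhouette from a contrast-backdrop image.

    Thresholds the image (Otsu when ``threshold`` is None; the heart is
    assumed darker than the backdrop unless ``dark_object`` is False),
    applies polygon edits in order — each a ``(vertices, "add"|"remove")``
    pair with vertices as (u, v) pixel coordinates — fills interior holes
    and keeps the largest connected component.

    Returns a uint8 binary mask (heart 1, background 0).
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise SegmentationError("image contains non-finite values")
    if threshold is None:
        if image.min() == image.max():
            raise SegmentationError("uniform image: empty silhouette")
        threshold = threshold_otsu(image)
    mask = image <= threshold if dark_object else image >= threshold

    if polygon_edits:
        for verts, mode in polygon_edits:
            verts = np.asarray(verts, dtype=float).reshape(-1, 2)
            poly = polygon2mask(image.shape, verts[:, ::-1])  # (u,v)->(r,c)
            if mode == "add":
                mask |= poly
            elif mode == "remove":
                mask &= ~poly
            else:
                raise ValueError(f"unknown polygon edit mode {mode!r}")

    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if keep_largest and mask.any():
        labels = cc_label(mask)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == np.argmax(counts)
    if not mask.any():
        raise SegmentationError("empty silhouette after thresholding")
    return mask.astype(np.uint8)


def assemble_stack(
    masks: np.ndarray | list[np.ndarray],
    start_angle: float,
    step: float,
    camera: CameraModel,
    rotation_axis: np.ndarray = (0.0, 0.0, 1.0),
    axis_point: np.ndarray = (0.0, 0.0, 0.0),
) -> SilhouetteStack:
    """Stack per-angle masks collected at a fixed angular step.

    ``angles[i] = start_angle + i * step``; all masks must share a shape.
    """
    if step <= 0:
        raise StackError("step must be positive")
    masks = [np.asarray(m) for m in masks]
    if len({m.shape for m in masks}) > 1:
        raise StackError("inconsistent stack: masks differ in shape")
    arr = np.stack(masks)
    angles = start_angle + step * np.arange(len(masks))
    return SilhouetteStack(
        masks=arr,
        angles=angles,
        camera=camera,
        rotation_axis=np.asarray(rotation_axis, dtype=float),
        axis_point=np.asarray(axis_point, dtype=float),
    )
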