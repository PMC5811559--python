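"""Texture-mapping of conditioned camera movies onto the surface mesh.

Each mesh face centroid is projected into every optical camera.  The
angle theta between the face normal (N_cell) and the camera viewing
direction (N_ic) classifies the face for that camera:

* theta <  90 degrees  -> excluded (face turned away),
* 90 <= theta <= 115   -> edge band (grazing view),
* theta > 115 degrees  -> assigned (face squarely toward the camera).

A face assigned to exactly one camera takes the trace of the closest
pixel of that camera.  Faces seen by several cameras (overlap, or in an
edge band) take a weighted average of the per-camera traces, with
weights read from each camera's radial gradient mask at the projected
pixel, which tapers camera influence toward its image edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera_geometry import (
    CameraModel,
    adjust_camera_pose,
    project_points_checked,
)
from .errors import ProjectionError
from .reconstruction import SurfaceMesh
from .signal_conditioning import OpticalMovie, WeightMask

__all__ = [
    "FaceAssignment",
    "ProjectedDataset",
    "classify_faces",
    "project_centroids",
    "assemble_projected_signals",
    "adjust_camera_pose",
    "ANGLE_EXCLUDE_DEG",
    "ANGLE_ASSIGN_DEG",
]

# printed classification thresholds (degrees between N_cell and N_ic)
ANGLE_EXCLUDE_DEG = 90.0
ANGLE_ASSIGN_DEG = 115.0


@dataclass
class FaceAssignment:
    """Camera assignment of one mesh face.

    ``klass`` is one of excluded / edge / assigned / overlap; ``cameras``
    lists (camera_id, (u, v) pixel, blend weight) for each contributing
    camera.
    """

    face_index: int
    klass: str
    cameras: list[tuple[str, tuple[int, int], float]]

    def __post_init__(self) -> None:
        if self.klass == "excluded" and self.cameras:
            raise ProjectionError("excluded faces carry no cameras")
        if self.klass == "assigned" and len(self.cameras) != 1:
            raise ProjectionError("assigned faces have exactly one camera")
        if self.klass == "overlap" and len(self.cameras) < 2:
            raise ProjectionError("overlap faces need >= 2 cameras")
        if any(w <= 0 for _, _, w in self.cameras):
            raise ProjectionError("blend weights must be positive")


@dataclass
class ProjectedDataset:
    """Per-face time series on the mesh with their camera assignments.

    ``signals`` is (N_cells, T); rows of excluded faces are NaN.
    """

    mesh: SurfaceMesh
    assignments: list[FaceAssignment]
    signals: np.ndarray
    sampling_rate: float

    @property
    def missing(self) -> np.ndarray:
        return np.array([a.klass == "excluded" for a in self.assignments])


def classify_faces(
    mesh: SurfaceMesh,
    camera: CameraModel,
    low: float = ANGLE_EXCLUDE_DEG,
    high: float = ANGLE_ASSIGN_DEG,
) -> np.ndarray:
    """Per-face class for one camera from the normal/view angle.

    Returns an array of strings: ``excluded`` (theta < low), ``edge``
    (low <= theta <= high, closed interval) or ``assigned``
    (theta > high), where theta = angle(N_cell, N_ic) in degrees.
    """
    n_ic = camera.optical_axis
    cosang = np.clip(mesh.face_normals @ n_ic, -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    out = np.where(theta < low, "excluded",
                   np.where(theta > high, "assigned", "edge"))
    return out


def project_centroids(
    mesh: SurfaceMesh, camera: CameraModel
) -> tuple[np.ndarray, np.ndarray]:
    """Project all face centroids into a camera.

    Returns (pixels, valid): ``pixels`` is (N_cells, 2) of nearest-integer
    (u, v); ``valid`` is False for centroids behind the camera or outside
    the frame (their pixel rows are -1).
    """
    uv, valid = project_points_checked(camera, mesh.face_centroids)
    w, h = camera.image_size
    pix = np.full((len(uv), 2), -1, dtype=int)
    if valid.any():
        pu = np.round(uv[valid, 0]).astype(int)
        pv = np.round(uv[valid, 1]).astype(int)
        ok = (pu >= 0) & (pu < w) & (pv >= 0) & (pv < h)
        sub = np.flatnonzero(valid)
        valid = np.zeros(len(uv), dtype=bool)
        valid[sub[ok]] = True
        pix[sub[ok], 0] = pu[ok]
        pix[sub[ok], 1] = pv[ok]
    return pix, valid


def assemble_projected_signals(
    mesh: SurfaceMesh,
    movies: dict[str, OpticalMovie],
    weight_masks: dict[str, WeightMask],
    cameras: dict[str, CameraModel],
    *,
    low: float = ANGLE_EXCLUDE_DEG,
    high: float = ANGLE_ASSIGN_DEG,
) -> ProjectedDataset:
    """Blend per-camera movies into per-face traces.

    For each face, cameras whose class is not ``excluded`` and whose
    projected pixel falls on that camera's foreground contribute their
    closest-pixel trace.  A single contributor is copied verbatim;
    multiple contributors are averaged with gradient-mask weights
    (sum w_i s_i / sum w_i).  The face class is ``assigned`` for one
    squarely-viewing camera, ``overlap`` when several cameras view it
    squarely, ``edge`` when only grazing views contribute, and
    ``excluded`` when no camera sees it (signal row NaN).
    """
    ids = sorted(movies)
    if set(ids) != set(cameras):
        raise ProjectionError("movies and cameras must share camera ids")
    lengths = {movies[i].n_samples for i in ids}
    if len(lengths) != 1:
        raise ProjectionError("length mismatch between camera movies")
    rates = {movies[i].sampling_rate for i in ids}
    if len(rates) != 1:
        raise ProjectionError("sampling-rate mismatch between camera movies")
    n_t = lengths.pop()

    klass = {i: classify_faces(mesh, cameras[i], low, high) for i in ids}
    pix = {}
    valid = {}
    for i in ids:
        pix[i], valid[i] = project_centroids(mesh, cameras[i])

    n_faces = mesh.n_cells
    signals = np.full((n_faces, n_t), np.nan)
    assignments: list[FaceAssignment] = []
    for fc in range(n_faces):
        contribs: list[tuple[str, tuple[int, int], float]] = []
        n_assigned = 0
        for i in ids:
            if klass[i][fc] == "excluded" or not valid[i][fc]:
                continue
            u, v = pix[i][fc]
            if movies[i].mask[v, u] == 0:
                continue
            wgt = float(weight_masks[i].weights[v, u])
            if wgt <= 0:
                continue
            contribs.append((i, (int(u), int(v)), wgt))
            if klass[i][fc] == "assigned":
                n_assigned += 1
        if not contribs:
            assignments.append(FaceAssignment(fc, "excluded", []))
            continue
        if len(contribs) == 1:
            i, (u, v), wgt = contribs[0]
            signals[fc] = movies[i].frames[v, u]
            kl = "assigned" if klass[i][fc] == "assigned" else "edge"
        else:
            num = np.zeros(n_t)
            den = 0.0
            for i, (u, v), wgt in contribs:
                num += wgt * movies[i].frames[v, u]
                den += wgt
            signals[fc] = num / den
            kl = "overlap" if n_assigned >= 2 else "edge"
        assignments.append(FaceAssignment(fc, kl, contribs))
    return ProjectedDataset(
        mesh=mesh,
        assignments=assignments,
        signals=signals,
        sampling_rate=float(rates.pop()),
    )
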