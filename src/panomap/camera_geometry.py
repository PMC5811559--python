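"""Pinhole camera model, calibration target and camera calibration.

The geometry pipeline uses a perspective (pinhole) camera: a world point
``p`` is moved into the camera frame by the extrinsic transform
``p_c = R p + t`` and then projected through the intrinsics

    u = f * x' + u0,     v = s * f * y' + v0

where ``x = X/Z, y = Y/Z`` are normalized image coordinates,
``x' = x (1 + k1 r^2)`` applies a single radial distortion coefficient
(``r^2 = x^2 + y^2``), ``f`` is the focal length in pixels, ``s`` the
aspect ratio and ``(u0, v0)`` the image center.

Cameras are calibrated against a gridded cuboid of known dimensions
centered at the world origin.  Grid-line intersections ("junctions")
detected in a calibration image are put in correspondence with their
known 3D positions, a direct linear transform (DLT) seeds the parameters
and a Levenberg-Marquardt refinement minimizes the reprojection error.

Conventions: the camera looks down its +z axis; pixel coordinates are
0-based with u to the right, v down, and pixel centers on integer
coordinates.  World units are those of the calibration cuboid (inches
for the default rabbit-scale target).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import rq
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation
from scipy.spatial import cKDTree
from skimage.feature import corner_harris, corner_peaks, corner_subpix

from .errors import CalibrationError, LabelingError, UnprojectablePointError

__all__ = [
    "CameraModel",
    "CalibrationCuboid",
    "JunctionObservations",
    "world_to_camera",
    "project_point",
    "detect_junctions",
    "label_junctions",
    "calibrate_camera",
    "reprojection_rmse",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CameraModel:
    """Perspective camera: extrinsics (R, t), intrinsics (f, s, u0, v0, k1).

    ``R`` maps world to camera coordinates (orthonormal, det +1), ``t`` is
    the translation in world units.  ``image_size`` is (width, height) in
    pixels.  ``k1`` is the first radial distortion coefficient in
    normalized image coordinates; the default 0 reflects optics with
    negligible distortion.
    """

    R: np.ndarray
    t: np.ndarray
    f: float
    s: float
    u0: float
    v0: float
    image_size: tuple[int, int]
    k1: float = 0.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-8):
            raise ValueError("R must be orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation (det +1)")
        if self.f <= 0 or self.s <= 0:
            raise ValueError("focal length and aspect ratio must be positive")

    @property
    def position(self) -> np.ndarray:
        """Camera center in world coordinates (-R^T t)."""
        return -self.R.T @ self.t

    @property
    def optical_axis(self) -> np.ndarray:
        """Unit viewing direction N_ic in world coordinates (+z of camera)."""
        return self.R.T @ np.array([0.0, 0.0, 1.0])

    def to_dict(self) -> dict:
        return {
            "R": self.R.tolist(),
            "t": self.t.tolist(),
            "f": float(self.f),
            "s": float(self.s),
            "u0": float(self.u0),
            "v0": float(self.v0),
            "k1": float(self.k1),
            "image_size": list(self.image_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            R=np.array(d["R"], dtype=float),
            t=np.array(d["t"], dtype=float),
            f=float(d["f"]),
            s=float(d["s"]),
            u0=float(d["u0"]),
            v0=float(d["v0"]),
            k1=float(d.get("k1", 0.0)),
            image_size=tuple(int(x) for x in d["image_size"]),
        )


@dataclass
class CalibrationCuboid:
    """Gridded rectangular cuboid used as the calibration target.

    The world origin sits at the cuboid center, +z along the height axis.
    Grid lines are ruled on the four vertical (outward-facing) faces at
    ``grid_spacing`` intervals, inset half a spacing from the face edges,
    so a face of width ``Wf`` and height ``H`` carries
    ``round(Wf / grid_spacing) x round(H / grid_spacing)`` junctions.
    The rabbit-scale default, 1 x 1 x 2 inches with 0.25-inch spacing,
    shows 32 junctions per face: a camera viewing two adjacent faces sees
    64 intersections.

    Faces are indexed in azimuthal order: 0 = +x, 1 = +y, 2 = -x, 3 = -y.
    Within a face, junction (i, j) has row ``i`` counting up the height
    axis and column ``j`` advancing counterclockwise (seen from +z).
    """

    L: float = 1.0
    W: float = 1.0
    H: float = 2.0
    grid_spacing: float = 0.25

    # face definitions: (outward normal, in-face column axis, origin sign)
    _FACE_NORMALS = (
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        np.array([-1.0, 0.0, 0.0]),
        np.array([0.0, -1.0, 0.0]),
    )
    # column direction advancing counterclockwise around +z
    _FACE_COLDIRS = (
        np.array([0.0, 1.0, 0.0]),
        np.array([-1.0, 0.0, 0.0]),
        np.array([0.0, -1.0, 0.0]),
        np.array([1.0, 0.0, 0.0]),
    )

    @property
    def n_rows(self) -> int:
        return int(round(self.H / self.grid_spacing))

    def face_width(self, face: int) -> float:
        return self.W if face in (0, 2) else self.L

    def n_cols(self, face: int) -> int:
        return int(round(self.face_width(face) / self.grid_spacing))

    def face_of(self, index: int) -> tuple[int, int, int]:
        """Decode a junction index into (face, row, col)."""
        for face in range(4):
            n = self.n_rows * self.n_cols(face)
            if index < n:
                return face, index // self.n_cols(face), index % self.n_cols(face)
            index -= n
        raise IndexError("junction index out of range")

    def junction_index(self, face: int, row: int, col: int) -> int:
        nc = self.n_cols(face)
        if not (0 <= row < self.n_rows and 0 <= col < nc):
            raise IndexError("junction (row, col) out of range")
        base = sum(self.n_rows * self.n_cols(fc) for fc in range(face))
        return base + row * nc + col

    def junction_position(self, face: int, row: int, col: int) -> np.ndarray:
        """3D world coordinates of junction (face, row, col)."""
        gs = self.grid_spacing
        normal = self._FACE_NORMALS[face]
        coldir = self._FACE_COLDIRS[face]
        half_out = (self.L if face in (0, 2) else self.W) / 2.0
        wf = self.face_width(face)
        a = -wf / 2.0 + (col + 0.5) * gs
        z = -self.H / 2.0 + (row + 0.5) * gs
        return normal * half_out + coldir * a + np.array([0.0, 0.0, z])

    @property
    def junction_coords(self) -> np.ndarray:
        """All junction positions, (N, 3), ordered by junction index."""
        pts = []
        for face in range(4):
            for row in range(self.n_rows):
                for col in range(self.n_cols(face)):
                    pts.append(self.junction_position(face, row, col))
        return np.array(pts)

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "W": self.W,
            "H": self.H,
            "grid_spacing": self.grid_spacing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCuboid":
        return cls(
            L=float(d["L"]), W=float(d["W"]), H=float(d["H"]),
            grid_spacing=float(d["grid_spacing"]),
        )


@dataclass
class JunctionObservations:
    """Sub-pixel junction detections with their 3D-junction labels.

    ``labels[i]`` indexes ``CalibrationCuboid.junction_coords``; -1 marks
    an unlabeled detection.
    """

    pixels: np.ndarray  # (N, 2) as (u, v)
    labels: np.ndarray  # (N,) int, -1 = unlabeled
    source_image: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if len(self.pixels) != len(self.labels):
            raise ValueError("pixels and labels must have equal length")
        lab = self.labels[self.labels >= 0]
        if len(np.unique(lab)) != len(lab):
            raise ValueError("duplicate junction labels")

    @property
    def labeled(self) -> "JunctionObservations":
        keep = self.labels >= 0
        return JunctionObservations(self.pixels[keep], self.labels[keep],
                                    self.source_image)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def world_to_camera(camera: CameraModel, point: np.ndarray) -> np.ndarray:
    """Apply the extrinsic (global-to-camera) transform R p + t.

    Accepts a single 3-vector or an (N, 3) array.
    """
    p = np.asarray(point, dtype=float)
    return p @ camera.R.T + camera.t


def project_point(camera: CameraModel, point: np.ndarray) -> np.ndarray:
    """Project world point(s) to pixel coordinates (u, v).

    Raises :class:`UnprojectablePointError` if any point maps to
    camera-frame depth Z <= 0.
    """
    pc = np.atleast_2d(world_to_camera(camera, point))
    if np.any(pc[:, 2] <= 0):
        raise UnprojectablePointError("point at or behind the camera plane")
    uv = _project_camera_frame(camera, pc)
    return uv[0] if np.asarray(point).ndim == 1 else uv


def _project_camera_frame(camera: CameraModel, pc: np.ndarray) -> np.ndarray:
    x = pc[:, 0] / pc[:, 2]
    y = pc[:, 1] / pc[:, 2]
    if camera.k1 != 0.0:
        r2 = x * x + y * y
        d = 1.0 + camera.k1 * r2
        x, y = x * d, y * d
    u = camera.f * x + camera.u0
    v = camera.s * camera.f * y + camera.v0
    return np.column_stack([u, v])


def project_points_checked(
    camera: CameraModel, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized projection that flags invalid points instead of raising.

    Returns (uv, valid) where ``valid`` is False for points with Z <= 0;
    their uv rows are NaN.  Used by the carving and texture-mapping loops
    where behind-camera points are expected and simply discarded.
    """
    pc = np.atleast_2d(
        np.asarray(points, dtype=float) @ camera.R.T + camera.t
    )
    valid = pc[:, 2] > 0
    uv = np.full((len(pc), 2), np.nan)
    if np.any(valid):
        uv[valid] = _project_camera_frame(camera, pc[valid])
    return uv, valid


# ---------------------------------------------------------------------------
# junction detection
# ---------------------------------------------------------------------------


def detect_junctions(
    image: np.ndarray,
    target_mask: np.ndarray,
    *,
    expected: int | None = None,
    threshold_rel: float = 0.02,
) -> np.ndarray:
    """Detect grid-line crossings inside ``target_mask``, sub-pixel refined.

    Runs a Harris corner detector restricted to the mask over a small
    ladder of smoothing scales (the projected grid pitch is not known a
    priori), refines each candidate set with
    :func:`skimage.feature.corner_subpix`, and merges refined detections
    closer than half the median genuine nearest-neighbor spacing.  Among
    the ladder results the most grid-regular set wins — the one whose
    nearest-neighbor spacings have the lowest coefficient of variation —
    with ``expected`` (junction count, when the caller knows the target)
    acting as a tie-breaking prior.

    Returns an (N, 2) array of (u, v) pixel coordinates.
    """
    image = np.asarray(image, dtype=float)
    target_mask = np.asarray(target_mask).astype(bool)
    if image.shape != target_mask.shape:
        raise ValueError("image and mask must share a shape")
    if not target_mask.any():
        warnings.warn("empty target mask: no junctions detected")
        return np.empty((0, 2))

    best_pts = np.empty((0, 2))
    best_score = np.inf
    for sigma in (1.0, 1.5):
        pts = _detect_once(image, target_mask, sigma, threshold_rel)
        if len(pts) < 4:
            continue
        d, _ = cKDTree(pts).query(pts, k=2)
        nn = d[:, 1]
        cv = float(np.std(nn) / np.mean(nn))
        score = cv
        if expected is not None:
            score += abs(len(pts) - expected) / expected
        if score < best_score:
            best_score, best_pts = score, pts
    return best_pts


def _cluster_centers(pts: np.ndarray, weights: np.ndarray,
                     cutoff: float) -> np.ndarray:
    """Weighted centers of single-linkage clusters at ``cutoff`` distance."""
    n = len(pts)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = cKDTree(pts).query_pairs(cutoff, output_type="ndarray")
    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    centers = []
    for r in np.unique(roots):
        sel = roots == r
        w = weights[sel]
        centers.append((pts[sel] * w[:, None]).sum(axis=0) / w.sum())
    return np.array(centers)


def _detect_once(
    image: np.ndarray,
    target_mask: np.ndarray,
    sigma: float,
    threshold_rel: float,
) -> np.ndarray:
    resp = corner_harris(image, sigma=sigma)
    resp = np.where(target_mask, resp, 0.0)
    peaks = corner_peaks(resp, min_distance=2, threshold_rel=threshold_rel)
    if len(peaks) < 2:
        return peaks[:, ::-1].astype(float)

    # a thick line crossing yields a small cluster of sub-corner
    # responses around the true junction (up to ~4), while distinct
    # junctions sit a full grid pitch apart; the distance to the 5th
    # neighbor estimates the pitch regardless of such clustering
    kq = min(6, len(peaks))
    dists, _ = cKDTree(peaks).query(peaks, k=kq)
    pitch_est = float(np.median(dists[:, kq - 1]))

    # refine every response with a window wide enough to span its whole
    # crossing: sub-corner siblings then converge onto the saddle point
    window = int(np.clip(round(0.8 * pitch_est), 5, 21)) | 1
    sub = corner_subpix(image, peaks, window_size=window, alpha=0.9)
    ok = ~np.isnan(sub[:, 0])
    pts_rc = np.where(ok[:, None], sub, peaks.astype(float))

    # collapse converged siblings (response-weighted mean)
    w = resp[peaks[:, 0], peaks[:, 1]]
    cutoff = max(0.4 * pitch_est, 2.0)
    centers = _cluster_centers(pts_rc, w, cutoff)
    return centers[:, ::-1]  # (row, col) -> (u, v)


# ---------------------------------------------------------------------------
# junction labeling
# ---------------------------------------------------------------------------


def _lattice_from_points(points: np.ndarray, n_rows: int) -> np.ndarray:
    """Assign integer (row, col) lattice coordinates to grid detections.

    Rows are recovered by splitting the v coordinate at the ``n_rows - 1``
    largest gaps (valid for near-equatorial viewing where grid rows do not
    overlap vertically); columns are ordered by u within each row.
    """
    n = len(points)
    if n % 1:  # pragma: no cover - points always integer-length
        raise LabelingError("empty point set")
    order_v = np.argsort(points[:, 1])
    v_sorted = points[order_v, 1]
    if n_rows > 1:
        gaps = np.diff(v_sorted)
        cut_idx = np.sort(np.argsort(-gaps)[: n_rows - 1])
        boundaries = np.concatenate([[0], cut_idx + 1, [n]])
    else:
        boundaries = np.array([0, n])
    lattice = np.empty((n, 2), dtype=int)
    for r in range(len(boundaries) - 1):
        members = order_v[boundaries[r]: boundaries[r + 1]]
        members = members[np.argsort(points[members, 0])]
        for c, idx in enumerate(members):
            lattice[idx] = (r, c)
    return lattice


def _facepair_unfolded(cuboid: CalibrationCuboid, fa: int) -> list[int]:
    """Junction indices of the two adjacent faces (fa, fa+1) unfolded into
    one grid, rows x (n_cols(fa) + n_cols(fb)) in counterclockwise column
    order; element [gi][gj] is a junction index."""
    fb = (fa + 1) % 4
    nca, ncb = cuboid.n_cols(fa), cuboid.n_cols(fb)
    out = []
    for gi in range(cuboid.n_rows):
        for gj in range(nca + ncb):
            if gj < nca:
                out.append(cuboid.junction_index(fa, gi, gj))
            else:
                out.append(cuboid.junction_index(fb, gi, gj - nca))
    return out


def label_junctions(
    points: np.ndarray,
    cuboid: CalibrationCuboid,
    anchors: list[tuple[np.ndarray, int]] | None = None,
) -> JunctionObservations:
    """Label detected junctions with their 3D grid indices.

    Without anchors the full two-face grid must be visible; every
    hypothesis (adjacent face pair x column direction x row direction) is
    scored by the reprojection error of a DLT camera fit and the best one
    wins.  With two anchors — a (pixel, junction index) pair for the
    top-left and bottom-right visible junctions, mirroring the two corner
    queries of the interactive workflow — labels are propagated along the
    lattice between them.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise LabelingError("no points to label")

    if anchors is not None and len(anchors) == 1:
        pix, lab = anchors[0]
        if len(points) != 1:
            raise LabelingError("single anchor only valid for a single point")
        return JunctionObservations(points, np.array([lab]))

    if anchors is None:
        return _label_full_grid(points, cuboid)
    return _label_with_anchors(points, cuboid, anchors)


def _label_full_grid(
    points: np.ndarray, cuboid: CalibrationCuboid
) -> JunctionObservations:
    n_rows = cuboid.n_rows
    n_expected = n_rows * (cuboid.n_cols(0) + cuboid.n_cols(1))
    if len(points) != n_expected:
        raise LabelingError(
            f"automatic labeling expects the full two-face grid "
            f"({n_expected} points), got {len(points)}"
        )
    lattice = _lattice_from_points(points, n_rows)
    coords = cuboid.junction_coords

    w = int(np.ceil(points[:, 0].max())) + 1
    h = int(np.ceil(points[:, 1].max())) + 1
    candidates: list[tuple[float, bool, int, np.ndarray]] = []
    hyp = 0
    for fa in range(4):
        grid = np.array(_facepair_unfolded(cuboid, fa)).reshape(n_rows, -1)
        for flip_rows in (False, True):
            for flip_cols in (False, True):
                g = grid[::-1] if flip_rows else grid
                g = g[:, ::-1] if flip_cols else g
                # image row 0 is the TOP of the image -> largest z
                labels = g[::-1][lattice[:, 0], lattice[:, 1]]
                world = coords[labels]
                try:
                    cam = _decompose_projection(_dlt(world, points), (w, h))
                except (np.linalg.LinAlgError, CalibrationError, ValueError):
                    continue
                pc = world @ cam.R.T + cam.t
                if np.any(pc[:, 2] <= 0):
                    continue
                rmse = float(np.sqrt(np.mean(np.sum(
                    (_project_camera_frame(cam, pc) - points) ** 2, axis=1))))
                # prefer an upright camera (image-down along world -z)
                # among hypotheses tied by reprojection error
                upright = cam.R[1] @ np.array([0.0, 0.0, -1.0]) > 0
                candidates.append((rmse, upright, hyp, labels))
                hyp += 1
    if not candidates:
        raise LabelingError("no consistent grid hypothesis found")
    best_rmse = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_rmse * 1.5 + 1e-9]
    tied.sort(key=lambda c: (not c[1], c[0], c[2]))
    return JunctionObservations(points, tied[0][3])


def _label_with_anchors(
    points: np.ndarray,
    cuboid: CalibrationCuboid,
    anchors: list[tuple[np.ndarray, int]],
) -> JunctionObservations:
    if len(anchors) != 2:
        raise LabelingError("anchored labeling needs exactly two anchors")
    (p1, j1), (p2, j2) = anchors
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    f1, i1, c1 = cuboid.face_of(j1)
    f2, i2, c2 = cuboid.face_of(j2)
    if f1 == f2:
        pair_starts = [f1, (f1 - 1) % 4]
    elif (f1 + 1) % 4 == f2:
        pair_starts = [f1]
    elif (f2 + 1) % 4 == f1:
        pair_starts = [f2]
    else:
        raise LabelingError("anchors lie on non-adjacent faces")

    for fa in pair_starts:
        grid = np.array(_facepair_unfolded(cuboid, fa)).reshape(cuboid.n_rows, -1)
        pos1 = np.argwhere(grid == j1)
        pos2 = np.argwhere(grid == j2)
        if len(pos1) == 0 or len(pos2) == 0:
            continue
        (gi1, gj1), (gi2, gj2) = pos1[0], pos2[0]
        d_rows = abs(gi1 - gi2) + 1
        lattice = _lattice_from_points(points, d_rows)
        a1 = lattice[np.argmin(np.linalg.norm(points - p1, axis=1))]
        a2 = lattice[np.argmin(np.linalg.norm(points - p2, axis=1))]
        if a1[0] == a2[0] or a1[1] == a2[1]:
            continue
        sr = (gi2 - gi1) / (a2[0] - a1[0])
        sc = (gj2 - gj1) / (a2[1] - a1[1])
        if abs(sr) != 1 or abs(sc) != 1:
            continue
        gi = gi1 + (lattice[:, 0] - a1[0]) * int(sr)
        gj = gj1 + (lattice[:, 1] - a1[1]) * int(sc)
        if gi.min() < 0 or gi.max() >= grid.shape[0]:
            continue
        if gj.min() < 0 or gj.max() >= grid.shape[1]:
            continue
        labels = grid[gi, gj]
        if len(np.unique(labels)) == len(labels):
            return JunctionObservations(points, labels)
    raise LabelingError("anchors inconsistent with any grid layout")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _dlt(world: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    """Direct linear transform: 3x4 projection matrix from >= 6 points."""
    n = len(world)
    A = np.zeros((2 * n, 12))
    X = np.hstack([world, np.ones((n, 1))])
    A[0::2, 0:4] = X
    A[0::2, 8:12] = -pixels[:, 0:1] * X
    A[1::2, 4:8] = X
    A[1::2, 8:12] = -pixels[:, 1:2] * X
    _, _, vt = np.linalg.svd(A)
    P = vt[-1].reshape(3, 4)
    # orient so that points sit in front of the camera
    if np.median(P[2, :3] @ world.T + P[2, 3]) < 0:
        P = -P
    return P


def _dlt_rmse(P: np.ndarray, world: np.ndarray, pixels: np.ndarray) -> float:
    proj = np.hstack([world, np.ones((len(world), 1))]) @ P.T
    with np.errstate(divide="ignore", invalid="ignore"):
        uv = proj[:, :2] / proj[:, 2:3]
    err = uv - pixels
    if not np.all(np.isfinite(err)):
        return np.inf
    return float(np.sqrt(np.mean(np.sum(err ** 2, axis=1))))


def _decompose_projection(
    P: np.ndarray, image_size: tuple[int, int]
) -> CameraModel:
    """Split a 3x4 projection matrix into R, t and constrained intrinsics.

    Assumes P is oriented so observed points have positive depth (the
    DLT enforces this); the matrix is rescaled so its third row — the
    camera z-row of [R|t] — has unit norm before the RQ split.  A
    remaining improper rotation means the correspondences are reflected
    (no real camera exists) and raises :class:`CalibrationError`.
    """
    P = P / np.linalg.norm(P[2, :3])
    K, R = rq(P[:, :3])
    signs = np.sign(np.diag(K))
    signs[signs == 0] = 1.0
    K = K * signs[np.newaxis, :]
    R = signs[:, np.newaxis] * R
    if np.linalg.det(R) < 0:
        raise CalibrationError(
            "projection matrix implies a reflected (improper) camera"
        )
    K = K / K[2, 2]
    t = np.linalg.solve(K, P[:, 3])
    f = abs(K[0, 0])
    s = abs(K[1, 1]) / f
    return CameraModel(
        R=R, t=t, f=f, s=s, u0=K[0, 2], v0=K[1, 2],
        image_size=image_size, k1=0.0,
    )


def _pack(camera: CameraModel, estimate_k1: bool) -> np.ndarray:
    rv = Rotation.from_matrix(camera.R).as_rotvec()
    p = [*rv, *camera.t, camera.f, camera.s, camera.u0, camera.v0]
    if estimate_k1:
        p.append(camera.k1)
    return np.array(p)


def _unpack(p: np.ndarray, image_size, estimate_k1: bool) -> CameraModel:
    R = Rotation.from_rotvec(p[0:3]).as_matrix()
    k1 = p[10] if estimate_k1 else 0.0
    return CameraModel(
        R=R, t=p[3:6], f=abs(p[6]), s=abs(p[7]), u0=p[8], v0=p[9],
        image_size=image_size, k1=k1,
    )


def calibrate_camera(
    obs: JunctionObservations,
    cuboid: CalibrationCuboid,
    init: CameraModel | None = None,
    *,
    image_size: tuple[int, int] | None = None,
    estimate_k1: bool = False,
    max_iterations: int = 200,
) -> CameraModel:
    """Solve for all camera parameters from labeled junction observations.

    A DLT estimate (unless ``init`` is given) seeds a Levenberg-Marquardt
    minimization of the stacked 2D reprojection residuals over rotation
    (as a rotation vector), translation, focal length, aspect ratio and
    image center; ``estimate_k1`` additionally frees the radial
    distortion coefficient.
    """
    labeled = obs.labeled
    if len(labeled.pixels) < 6:
        raise CalibrationError("at least 6 labeled correspondences required")
    world = cuboid.junction_coords[labeled.labels]
    pixels = labeled.pixels
    if np.linalg.matrix_rank(world - world.mean(axis=0)) < 2:
        raise CalibrationError("degenerate (collinear) junction configuration")

    if init is None:
        P = _dlt(world, pixels)
        if image_size is None:
            w = int(np.ceil(pixels[:, 0].max())) + 1
            h = int(np.ceil(pixels[:, 1].max())) + 1
            image_size = (w, h)
        try:
            init = _decompose_projection(P, image_size)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise CalibrationError(f"DLT initialization failed: {exc}") from exc
    elif image_size is None:
        image_size = init.image_size

    def residuals(p: np.ndarray) -> np.ndarray:
        cam = _unpack(p, image_size, estimate_k1)
        pc = world @ cam.R.T + cam.t
        bad = pc[:, 2] <= 1e-9
        pc[bad, 2] = 1e-9
        uv = _project_camera_frame(cam, pc)
        res = (uv - pixels).ravel()
        res[np.repeat(bad, 2)] = 1e6
        return res

    sol = least_squares(
        residuals,
        _pack(init, estimate_k1),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_iterations * 20,
    )
    return _unpack(sol.x, image_size, estimate_k1)


def reprojection_rmse(
    camera: CameraModel,
    obs: JunctionObservations,
    cuboid: CalibrationCuboid,
) -> float:
    """Root-mean-square reprojection error (pixels) over labeled points."""
    labeled = obs.labeled
    if len(labeled.pixels) == 0:
        raise CalibrationError("no labeled observations")
    world = cuboid.junction_coords[labeled.labels]
    uv = project_point(camera, world)
    err = uv - labeled.pixels
    return float(np.sqrt(np.mean(np.sum(err ** 2, axis=1))))


def adjust_camera_pose(
    camera: CameraModel,
    delta_rotation_deg: np.ndarray,
    delta_translation: np.ndarray,
) -> CameraModel:
    """Compose small user alignment corrections onto a camera pose.

    ``delta_rotation_deg`` are xyz Euler angles in degrees applied in the
    camera frame; ``delta_translation`` is added to t.  Zero deltas return
    an identical camera.
    """
    dR = Rotation.from_euler("xyz", np.asarray(delta_rotation_deg, float),
                             degrees=True).as_matrix()
    return replace(
        camera,
        R=dR @ camera.R,
        t=dR @ camera.t + np.asarray(delta_translation, dtype=float),
    )
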