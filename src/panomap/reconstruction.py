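"""Visual-hull reconstruction of the epicardial surface.

The silhouettes collected while rotating the heart define an occluding
cone per view; the heart volume is (conservatively) their intersection,
the visual hull.  A cube slightly larger than the heart and centered at
the world origin is carved by an octree: a voxel whose corners all
project inside every silhouette is inside, one that projects entirely
outside some silhouette is outside, and boundary voxels are subdivided
until the target resolution, where they receive occupancy 0.5 so the
isosurface passes through them.  Coarse voxels are only accepted as
inside/outside when a distance-transform bound proves every point of the
voxel (not just its corners) shares that classification, so the octree
result is identical to exhaustively classifying the finest grid.

Marching cubes turns the occupancy field into a watertight triangulated
mesh, optionally relaxed by volume-preserving Taubin smoothing, and
per-face centroids and outward normals feed the texture-mapping stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .camera_geometry import CameraModel, project_points_checked
from .errors import CarvingError, MeshError
from .silhouette import SilhouetteStack

__all__ = [
    "OccupancyVolume",
    "SurfaceMesh",
    "classify_voxel",
    "carve_visual_hull",
    "carve_dense",
    "extract_surface",
    "smooth_surface",
    "compute_face_frames",
    "default_bounds",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OccupancyVolume:
    """Carved occupancy on the finest octree grid.

    ``occupancy[i, j, k]`` covers the cell with world extent
    ``origin + [i, j, k] * resolution`` to ``origin + [i+1, j+1, k+1] *
    resolution``; values are 1 (inside), 0 (outside) or 0.5 (boundary at
    maximum depth).
    """

    origin: np.ndarray
    resolution: float
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)

    @property
    def extent(self) -> np.ndarray:
        return np.array(self.occupancy.shape) * self.resolution

    @property
    def volume(self) -> float:
        """Enclosed volume estimate: full cells plus half of boundary cells."""
        return float(self.occupancy.sum()) * self.resolution ** 3


@dataclass
class SurfaceMesh:
    """Triangulated epicardial surface with per-face frames.

    Watertight, consistently wound (signed volume positive); normals
    point outward.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self._tm: trimesh.Trimesh | None = None

    def to_trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(vertices=np.array(tm.vertices), faces=np.array(tm.faces))

    @property
    def n_cells(self) -> int:
        return len(self.faces)

    @property
    def n_verts(self) -> int:
        return len(self.vertices)

    @property
    def face_centroids(self) -> np.ndarray:
        return self.to_trimesh().triangles_center

    @property
    def face_normals(self) -> np.ndarray:
        return self.to_trimesh().face_normals

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    @property
    def enclosed_volume(self) -> float:
        return float(self.to_trimesh().volume)

    @property
    def euler_characteristic(self) -> int:
        return int(self.to_trimesh().euler_number)


# ---------------------------------------------------------------------------
# silhouette sampling
# ---------------------------------------------------------------------------


def _axis_rotations(stack: SilhouetteStack) -> list[np.ndarray]:
    axis = stack.rotation_axis
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    mats = []
    for ang in np.deg2rad(stack.angles):
        mats.append(np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K)
    return mats


def points_inside_hull(points: np.ndarray, stack: SilhouetteStack
                       ) -> np.ndarray:
    """Exact visual-hull membership of world points.

    A point is inside iff, for EVERY stage angle, rotating it with the
    stage and projecting through the geometry camera lands on a
    silhouette (nearest-pixel lookup); projections outside the image
    count as outside the silhouette.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cam = stack.camera
    h, w = stack.shape
    inside = np.ones(len(points), dtype=bool)
    ap = stack.axis_point
    for Rm, mask in zip(_axis_rotations(stack), stack.masks):
        if not inside.any():
            break
        idx = np.flatnonzero(inside)
        p = (points[idx] - ap) @ Rm.T + ap
        uv, valid = project_points_checked(cam, p)
        ok = valid.copy()
        if ok.any():
            ui = np.round(uv[ok, 0]).astype(int)
            vi = np.round(uv[ok, 1]).astype(int)
            in_img = (ui >= 0) & (ui < w) & (vi >= 0) & (vi < h)
            hit = np.zeros(ok.sum(), dtype=bool)
            hit[in_img] = mask[vi[in_img], ui[in_img]] > 0
            ok[ok] = hit
        inside[idx[~ok]] = False
    return inside


def classify_voxel(corners: np.ndarray, stack: SilhouetteStack) -> str:
    """Classify one voxel from its 8 corners: inside/outside/boundary."""
    if len(stack) == 0:
        raise CarvingError("empty silhouette stack")
    ins = points_inside_hull(np.asarray(corners, dtype=float).reshape(8, 3),
                             stack)
    if ins.all():
        return "inside"
    if not ins.any():
        return "outside"
    return "boundary"


# ---------------------------------------------------------------------------
# carving
# ---------------------------------------------------------------------------


def default_bounds(stack: SilhouetteStack, margin: float = 1.2
                   ) -> tuple[np.ndarray, float]:
    """Cube centered on the axis point sized from the silhouette extents.

    Back-projects the largest silhouette radius (about the principal
    point) to the axis distance and scales by ``margin`` ("slightly
    larger than the heart").  Returns (origin, side).
    """
    cam = stack.camera
    dist = float(np.linalg.norm(cam.position - stack.axis_point))
    h, w = stack.shape
    max_r = 0.0
    for mask in stack.masks:
        vi, ui = np.nonzero(mask)
        if len(ui) == 0:
            raise CarvingError("degenerate silhouette in stack")
        r = np.hypot((ui - cam.u0) / cam.f,
                     (vi - cam.v0) / (cam.s * cam.f)).max()
        max_r = max(max_r, float(r))
    half = margin * max_r * dist
    side = 2 * half
    origin = stack.axis_point - half
    return origin, side


def carve_visual_hull(
    stack: SilhouetteStack,
    bounds: tuple[np.ndarray, float] | None = None,
    max_depth: int = 7,
) -> OccupancyVolume:
    """Octree visual-hull carve to ``2**max_depth`` cells per edge.

    Coarse cells are finalized only when a Euclidean-distance-transform
    bound on each silhouette proves that the whole cell projects inside
    (or some view proves it entirely outside); everything else is
    subdivided, so the occupancy equals brute-force classification of
    the finest grid (:func:`carve_dense`).
    """
    if max_depth < 1:
        raise CarvingError("max_depth must be >= 1")
    if len(stack) == 0:
        raise CarvingError("empty silhouette stack")
    if not stack.masks.any(axis=(1, 2)).all():
        raise CarvingError("degenerate silhouette in stack")
    if bounds is None:
        bounds = default_bounds(stack)
    origin, side = np.asarray(bounds[0], dtype=float), float(bounds[1])

    n = 2 ** max_depth
    res = side / n
    occ = np.zeros((n, n, n), dtype=float)

    cam = stack.camera
    h, w = stack.shape
    rots = _axis_rotations(stack)
    # distance (px) to the nearest background / foreground pixel
    dist_in = [ndimage.distance_transform_edt(m) for m in stack.masks]
    dist_out = [ndimage.distance_transform_edt(1 - m) for m in stack.masks]
    ap = stack.axis_point

    def conservative(cells: np.ndarray, depth: int
                     ) -> tuple[np.ndarray, np.ndarray]:
        """(provably inside, provably outside) for cell index triples."""
        size = side / (2 ** depth)
        centers = origin + (cells + 0.5) * size
        r_world = size * np.sqrt(3) / 2.0
        inside = np.ones(len(cells), dtype=bool)
        outside = np.zeros(len(cells), dtype=bool)
        feff = cam.f * max(cam.s, 1.0)
        for Rm, din, dout in zip(rots, dist_in, dist_out):
            p = (centers - ap) @ Rm.T + ap
            uv, valid = project_points_checked(cam, p)
            z = (p @ cam.R.T + cam.t)[:, 2]
            margin = r_world * feff / np.maximum(z - r_world, 1e-9) + 1.5
            ui = np.round(np.nan_to_num(uv[:, 0], nan=-1e9)).astype(np.int64)
            vi = np.round(np.nan_to_num(uv[:, 1], nan=-1e9)).astype(np.int64)
            in_img = valid & (ui >= 0) & (ui < w) & (vi >= 0) & (vi < h)
            di = np.zeros(len(cells))
            do = np.zeros(len(cells))
            di[in_img] = din[vi[in_img], ui[in_img]]
            do[in_img] = dout[vi[in_img], ui[in_img]]
            # off-image distance to the image rectangle (conservative)
            off = ~in_img & valid
            if off.any():
                du = np.maximum(np.maximum(-uv[off, 0], uv[off, 0] - (w - 1)), 0)
                dv = np.maximum(np.maximum(-uv[off, 1], uv[off, 1] - (h - 1)), 0)
                do[off] = np.hypot(du, dv)
            do[~valid] = np.inf  # behind camera: surely outside this cone
            inside &= in_img & (di > margin)
            outside |= (do > margin) | ~valid
        return inside & ~outside, outside

    # breadth-first octree over cell index triples
    cells = np.array([[0, 0, 0]], dtype=np.int64)
    for depth in range(0, max_depth):
        scale = n // (2 ** depth)
        ins, outs = conservative(cells, depth)
        for sel, val in ((ins, 1.0),):
            for c in cells[sel]:
                i, j, k = c * scale
                occ[i:i + scale, j:j + scale, k:k + scale] = val
        mixed = cells[~ins & ~outs]
        if len(mixed) == 0:
            cells = mixed
            break
        # subdivide
        offs = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                         for k in (0, 1)], dtype=np.int64)
        cells = (mixed[:, None, :] * 2 + offs[None, :, :]).reshape(-1, 3)

    if len(cells):
        occ = _finalize_finest(occ, cells, origin, res, stack)
    return OccupancyVolume(origin=origin, resolution=res, occupancy=occ)


def _finalize_finest(
    occ: np.ndarray,
    cells: np.ndarray,
    origin: np.ndarray,
    res: float,
    stack: SilhouetteStack,
) -> np.ndarray:
    """Exact 8-corner classification of the remaining finest cells."""
    # unique corner lattice points shared between neighboring cells
    offs = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                     for k in (0, 1)], dtype=np.int64)
    corner_idx = (cells[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    uniq, inv = np.unique(corner_idx, axis=0, return_inverse=True)
    pts = origin + uniq * res
    ins = points_inside_hull(pts, stack)
    cins = ins[inv].reshape(len(cells), 8)
    vals = np.where(cins.all(axis=1), 1.0,
                    np.where(~cins.any(axis=1), 0.0, 0.5))
    occ[cells[:, 0], cells[:, 1], cells[:, 2]] = vals
    return occ


def carve_dense(
    stack: SilhouetteStack,
    bounds: tuple[np.ndarray, float],
    max_depth: int,
) -> OccupancyVolume:
    """Brute-force carve: classify every finest-grid cell by its corners.

    Independent reference for :func:`carve_visual_hull`; cost grows as
    ``8**max_depth`` so keep the depth small.
    """
    origin, side = np.asarray(bounds[0], dtype=float), float(bounds[1])
    n = 2 ** max_depth
    res = side / n
    ii = np.arange(n + 1)
    gi, gj, gk = np.meshgrid(ii, ii, ii, indexing="ij")
    pts = origin + np.stack([gi, gj, gk], axis=-1).reshape(-1, 3) * res
    ins = points_inside_hull(pts, stack).reshape(n + 1, n + 1, n + 1)
    c = np.zeros((n, n, n), dtype=int)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                c += ins[di:n + di, dj:n + dj, dk:n + dk]
    occ = np.where(c == 8, 1.0, np.where(c == 0, 0.0, 0.5))
    return OccupancyVolume(origin=origin, resolution=res, occupancy=occ)


# ---------------------------------------------------------------------------
# surface extraction and smoothing
# ---------------------------------------------------------------------------


def extract_surface(volume: OccupancyVolume, iso: float = 0.5) -> SurfaceMesh:
    """Marching-cubes isosurface of the carved occupancy.

    The field is sampled at cell centers and zero-padded so the surface
    closes even if occupancy touches the volume edge.  The mesh is
    cleaned (duplicate vertices merged, degenerate faces dropped) and
    wound so the signed volume is positive with outward normals.
    """
    occ = volume.occupancy
    if occ.min() >= iso or occ.max() <= iso:
        raise MeshError("occupancy field has no isosurface at this level")
    pad = np.pad(occ, 1, mode="constant")
    verts, faces, _, _ = marching_cubes(pad, level=iso)
    # cell centers: padded index i maps to world origin + (i - 0.5) * res
    verts = volume.origin + (verts - 0.5) * volume.resolution
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    trimesh.repair.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()
    if not tm.is_watertight:
        trimesh.repair.fill_holes(tm)
    return SurfaceMesh.from_trimesh(tm)


def smooth_surface(
    mesh: SurfaceMesh,
    iterations: int = 50,
    lam: float = 0.5,
    mu: float = -0.53,
) -> SurfaceMesh:
    """Taubin lambda|mu smoothing (shrink-compensated Laplacian).

    Alternates inflation (``lam`` > 0) and deflation (``mu`` < 0) passes
    so the enclosed volume is approximately preserved; connectivity and
    vertex count are unchanged.  ``iterations=0`` returns an identical
    mesh.
    """
    if iterations == 0:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())
    tm = trimesh.Trimesh(vertices=mesh.vertices.copy(),
                         faces=mesh.faces.copy(), process=False)
    trimesh.smoothing.filter_taubin(tm, lamb=lam, nu=-mu,
                                    iterations=iterations)
    return SurfaceMesh(vertices=np.array(tm.vertices), faces=mesh.faces.copy())


def compute_face_frames(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-face centroids (vertex means) and unit outward normals."""
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1)
    bad = np.flatnonzero(norms < 1e-14)
    if len(bad):
        raise MeshError(f"degenerate (zero-area) face at index {bad[0]}")
    normals = normals / norms[:, None]
    # orient outward: flip any normal pointing against the winding-derived
    # trimesh normal (which is outward for positive signed volume)
    ref = mesh.face_normals
    flip = np.sum(normals * ref, axis=1) < 0
    normals[flip] = -normals[flip]
    return centroids, normals
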