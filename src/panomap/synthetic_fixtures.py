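"""Synthetic inputs with exact ground truth for the whole pipeline.

Real panoramic optical-mapping inputs (calibration photographs, rotation
silhouettes of a perfused heart, and voltage-dye movies) require animals
and hardware; every consumer in this package is therefore exercised
against rendered stand-ins whose ground truth is known in closed form:

* ray-cast images of the gridded calibration cuboid, with the exact
  sub-pixel position and label of every visible grid junction;
* rotation silhouettes of analytic solids (sphere, ellipsoid, cuboid)
  via exact ray-solid intersection tests;
* optical movies carrying parametric action potentials organized as
  plane waves, paced focal activations or spiral waves, rendered to each
  camera by ray casting with the per-face ground-truth signal returned
  alongside.

The action-potential template is piecewise linear (baseline, linear
upstroke, plateau, linear repolarization): closed-form APD at any
repolarization level beats biophysical realism for validation purposes.
All generators are deterministic given their seed.

The default four-camera rig places optical cameras at 90-degree azimuth
spacing around the rotation axis, mirroring the physical enclosure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .camera_geometry import (
    CalibrationCuboid,
    CameraModel,
    JunctionObservations,
    project_point,
)
from .errors import PanomapError
from .signal_conditioning import OpticalMovie
from .silhouette import SilhouetteStack

__all__ = [
    "AnalyticSolid",
    "APTemplate",
    "make_ring_camera",
    "make_camera_ring",
    "render_calibration_target",
    "render_rotation_silhouettes",
    "synth_action_potential",
    "synth_camera_movies",
    "synth_spiral_phase_field",
    "single_face_mesh",
]


# ---------------------------------------------------------------------------
# cameras
# ---------------------------------------------------------------------------


def make_ring_camera(
    azimuth_deg: float,
    distance: float,
    *,
    elevation_deg: float = 0.0,
    f: float = 300.0,
    s: float = 1.0,
    image_size: tuple[int, int] = (200, 200),
    k1: float = 0.0,
) -> CameraModel:
    """Camera on a ring around the world +z axis, aimed at the origin.

    Azimuth 0 places the camera on the +x axis; image v points along
    world -z (hanging-heart apex down appears image-down).
    """
    az = np.deg2rad(azimuth_deg)
    el = np.deg2rad(elevation_deg)
    pos = distance * np.array(
        [np.cos(az) * np.cos(el), np.sin(az) * np.cos(el), np.sin(el)]
    )
    forward = -pos / np.linalg.norm(pos)
    world_down = np.array([0.0, 0.0, -1.0])
    xc = np.cross(world_down, forward)
    nx = np.linalg.norm(xc)
    if nx < 1e-12:
        raise PanomapError("camera axis parallel to rotation axis")
    xc = xc / nx
    yc = np.cross(forward, xc)
    R = np.stack([xc, yc, forward])
    w, h = image_size
    return CameraModel(
        R=R, t=-R @ pos, f=f, s=s,
        u0=(w - 1) / 2.0, v0=(h - 1) / 2.0,
        image_size=image_size, k1=k1,
    )


def make_camera_ring(
    n_cameras: int = 4,
    distance: float = 8.0,
    *,
    start_azimuth_deg: float = 0.0,
    f: float = 300.0,
    image_size: tuple[int, int] = (100, 100),
) -> dict[str, CameraModel]:
    """The standard rig: ``n_cameras`` at even azimuthal spacing."""
    ids = [chr(ord("A") + i) for i in range(n_cameras)]
    return {
        cid: make_ring_camera(
            start_azimuth_deg + 360.0 * i / n_cameras, distance,
            f=f, image_size=image_size,
        )
        for i, cid in enumerate(ids)
    }


def _pixel_rays(camera: CameraModel, supersample: int = 1
                ) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """World-frame origin and per-pixel unit ray directions.

    Returns (origin (3,), dirs (H*ss, W*ss, 3), grid shape).  Supersampled
    grids place ``supersample**2`` rays per pixel for anti-aliasing.
    """
    w, h = camera.image_size
    ss = supersample
    us = (np.arange(w * ss) + 0.5) / ss - 0.5
    vs = (np.arange(h * ss) + 0.5) / ss - 0.5
    uu, vv = np.meshgrid(us, vs)
    x = (uu - camera.u0) / camera.f
    y = (vv - camera.v0) / (camera.s * camera.f)
    if camera.k1 != 0.0:
        # invert the radial model by fixed point iteration
        xd, yd = x.copy(), y.copy()
        for _ in range(10):
            r2 = xd * xd + yd * yd
            xd = x / (1.0 + camera.k1 * r2)
            yd = y / (1.0 + camera.k1 * r2)
        x, y = xd, yd
    dirs_cam = np.stack([x, y, np.ones_like(x)], axis=-1)
    dirs = dirs_cam @ camera.R  # R^T applied to each row vector
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    return camera.position, dirs, (h * ss, w * ss)


# ---------------------------------------------------------------------------
# analytic solids
# ---------------------------------------------------------------------------


@dataclass
class AnalyticSolid:
    """Sphere, ellipsoid or cuboid with exact inside and ray tests.

    ``params``: sphere -> {"radius"}; ellipsoid -> {"semi_axes": (a,b,c)};
    cuboid -> {"dimensions": (L,W,H)}.  ``center`` translates the solid;
    ``orientation`` (3x3 rotation) poses it.  All kinds are convex.
    """

    kind: str
    params: dict
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    convex: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "ellipsoid", "cuboid"):
            raise PanomapError(f"unknown solid kind {self.kind!r}")
        self.center = np.asarray(self.center, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)

    def _semi_axes(self) -> np.ndarray:
        if self.kind == "sphere":
            r = float(self.params["radius"])
            return np.array([r, r, r])
        if self.kind == "ellipsoid":
            return np.asarray(self.params["semi_axes"], dtype=float)
        return np.asarray(self.params["dimensions"], dtype=float) / 2.0

    def _to_local(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self.center) @ self.orientation

    def inside(self, pts: np.ndarray) -> np.ndarray:
        """Exact membership test for (..., 3) points."""
        pts = np.asarray(pts, dtype=float)
        q = self._to_local(pts.reshape(-1, 3))
        ax = self._semi_axes()
        if self.kind == "cuboid":
            ok = np.all(np.abs(q) <= ax, axis=-1)
        else:
            ok = np.sum((q / ax) ** 2, axis=-1) <= 1.0
        return ok.reshape(pts.shape[:-1])

    def ray_hits(self, origin: np.ndarray, dirs: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        """First positive intersection of rays from ``origin``.

        ``dirs`` is (..., 3); returns (hit mask, t of first hit with NaN
        where missed), both of shape ``dirs.shape[:-1]``.
        """
        shape = np.asarray(dirs).shape[:-1]
        d = np.asarray(dirs, dtype=float).reshape(-1, 3) @ self.orientation
        o = self._to_local(np.asarray(origin, dtype=float).reshape(1, 3))
        ax = self._semi_axes()
        if self.kind == "cuboid":
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = (-ax - o) / d
                t2 = (ax - o) / d
            tmin = np.nanmax(np.minimum(t1, t2), axis=-1)
            tmax = np.nanmin(np.maximum(t1, t2), axis=-1)
            hit = (tmax >= tmin) & (tmax > 0)
            t = np.where(tmin > 0, tmin, tmax)
        else:
            os = o / ax
            ds = d / ax
            a = np.sum(ds * ds, axis=-1)
            b = 2.0 * np.sum(os * ds, axis=-1)
            c = float(np.sum(os * os)) - 1.0
            disc = b * b - 4 * a * c
            hit = disc >= 0
            sq = np.sqrt(np.where(hit, disc, 0.0))
            t1 = (-b - sq) / (2 * a)
            t2 = (-b + sq) / (2 * a)
            t = np.where(t1 > 0, t1, t2)
            hit &= t > 0
        t = np.where(hit, t, np.nan)
        return hit.reshape(shape), t.reshape(shape)


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


# ---------------------------------------------------------------------------
# calibration target rendering
# ---------------------------------------------------------------------------


def render_calibration_target(
    camera: CameraModel,
    cuboid: CalibrationCuboid,
    *,
    line_width: float = 0.02,
    supersample: int = 3,
    background: float = 0.35,
    face_bright: float = 0.95,
    line_dark: float = 0.05,
) -> tuple[np.ndarray, JunctionObservations, np.ndarray]:
    """Ray-cast image of the gridded cuboid plus exact junction truth.

    Grid lines of world-unit half-width ``line_width`` are drawn on the
    four vertical faces at the cuboid's junction rows/columns.  Returns
    ``(image, truth, target_mask)`` where ``truth`` holds the exact
    projected sub-pixel location and label of every junction on a face
    oriented toward the camera, and ``target_mask`` covers the visible
    cuboid interior (slightly eroded so the occluding outline is not
    mistaken for grid structure).
    """
    solid = AnalyticSolid(
        "cuboid", {"dimensions": (cuboid.L, cuboid.W, cuboid.H)}
    )
    origin, dirs, grid_shape = _pixel_rays(camera, supersample)
    hit, t = solid.ray_hits(origin, dirs)
    pts = origin + np.nan_to_num(t)[..., None] * dirs

    # face coordinates for shading
    img = np.full(grid_shape, background)
    gs = cuboid.grid_spacing
    half = np.array([cuboid.L / 2, cuboid.W / 2, cuboid.H / 2])
    for face in range(4):
        normal = cuboid._FACE_NORMALS[face]
        coldir = cuboid._FACE_COLDIRS[face]
        on_face = hit & (
            np.abs(pts @ normal - np.abs(normal @ half)) < 1e-9
        )
        if not on_face.any():
            continue
        a = pts[on_face] @ coldir  # in-face horizontal coordinate
        z = pts[on_face][:, 2]
        wf = cuboid.face_width(face)
        # grid lines run through the junction rows and columns
        da = np.abs((a + wf / 2 - 0.5 * gs) % gs)
        da = np.minimum(da, gs - da)
        dz = np.abs((z + cuboid.H / 2 - 0.5 * gs) % gs)
        dz = np.minimum(dz, gs - dz)
        near_line = np.minimum(da, dz) <= line_width
        shade = np.where(near_line, line_dark, face_bright)
        img[on_face] = shade

    # average supersamples down to the true pixel grid
    w, h = camera.image_size
    ss = supersample
    img = img.reshape(h, ss, w, ss).mean(axis=(1, 3))
    hit_frac = hit.reshape(h, ss, w, ss).mean(axis=(1, 3))

    # mask: fully-on-target pixels, eroded away from the outline
    from scipy import ndimage as _ndi

    target_mask = _ndi.binary_erosion(hit_frac >= 1.0, iterations=3)

    # ground truth: junctions on faces oriented toward the camera
    pix, labels = [], []
    cam_pos = camera.position
    visible_faces = [
        fc for fc in range(4)
        if cuboid._FACE_NORMALS[fc] @ (cam_pos - cuboid._FACE_NORMALS[fc]
                                       * float(cuboid._FACE_NORMALS[fc] @ half)) > 0
    ]
    for face in visible_faces:
        for row in range(cuboid.n_rows):
            for col in range(cuboid.n_cols(face)):
                p3 = cuboid.junction_position(face, row, col)
                uv = project_point(camera, p3)
                if 0 <= uv[0] <= w - 1 and 0 <= uv[1] <= h - 1:
                    pix.append(uv)
                    labels.append(cuboid.junction_index(face, row, col))
    truth = JunctionObservations(
        np.array(pix).reshape(-1, 2), np.array(labels, dtype=int)
    )
    return img, truth, target_mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# rotation silhouettes
# ---------------------------------------------------------------------------


def render_rotation_silhouettes(
    solid: AnalyticSolid,
    camera: CameraModel,
    angles: np.ndarray,
    *,
    rotation_axis: np.ndarray = (0.0, 0.0, 1.0),
    axis_point: np.ndarray = (0.0, 0.0, 0.0),
    require_in_frame: bool = True,
) -> SilhouetteStack:
    """Exact silhouettes of ``solid`` rotated to each stage angle.

    A mask pixel is 1 iff the pixel-center ray intersects the solid
    rotated by that angle about the axis (rays are inverse-rotated, the
    solid stays fixed).  The convention matches the carver: stage angle a
    maps a body point p to ``R_axis(a) (p - axis_point) + axis_point``.
    """
    angles = np.asarray(angles, dtype=float)
    origin, dirs, grid_shape = _pixel_rays(camera, 1)
    axis_point = np.asarray(axis_point, dtype=float)
    masks = []
    flat_dirs = dirs.reshape(-1, 3)
    for ang in angles:
        Rinv = _axis_rotation(rotation_axis, -ang)
        o = Rinv @ (origin - axis_point) + axis_point
        d = flat_dirs @ Rinv.T
        hit, _ = solid.ray_hits(o, d.reshape(dirs.shape))
        mask = hit.reshape(grid_shape).astype(np.uint8)
        if require_in_frame:
            if not mask.any():
                raise PanomapError(f"solid out of frame at angle {ang}")
            if (mask[0].any() or mask[-1].any()
                    or mask[:, 0].any() or mask[:, -1].any()):
                raise PanomapError(f"solid clipped by frame at angle {ang}")
        masks.append(mask)
    return SilhouetteStack(
        masks=np.stack(masks),
        angles=angles,
        camera=camera,
        rotation_axis=np.asarray(rotation_axis, dtype=float),
        axis_point=axis_point,
    )


# ---------------------------------------------------------------------------
# action potentials and movies
# ---------------------------------------------------------------------------


@dataclass
class APTemplate:
    """Piecewise-linear optical action potential (times in ms).

    baseline until ``upstroke_time``, linear rise over
    ``upstroke_duration`` to ``baseline + amplitude``, flat plateau,
    linear repolarization back to baseline.
    """

    upstroke_time: float = 20.0
    upstroke_duration: float = 2.0
    amplitude: float = 1.0
    plateau_duration: float = 80.0
    repolarization_duration: float = 100.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        for name in ("upstroke_duration", "plateau_duration",
                     "repolarization_duration"):
            if getattr(self, name) < 0:
                raise PanomapError(f"{name} must be non-negative")

    @property
    def activation_time(self) -> float:
        """Maximum-derivative time: the middle of the linear upstroke."""
        return self.upstroke_time + self.upstroke_duration / 2.0

    def apd(self, level: float = 0.8) -> float:
        """Closed-form APD: time from activation to repolarization to
        ``level`` (trace falling below peak - level * amplitude)."""
        t_cross = (self.upstroke_time + self.upstroke_duration
                   + self.plateau_duration
                   + level * self.repolarization_duration)
        return t_cross - self.activation_time

    def evaluate(self, times_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(times_ms, dtype=float)
        t0 = self.upstroke_time
        t1 = t0 + self.upstroke_duration
        t2 = t1 + self.plateau_duration
        t3 = t2 + self.repolarization_duration
        out = np.full(t.shape, self.baseline, dtype=float)
        if self.upstroke_duration > 0:
            rising = (t >= t0) & (t < t1)
            out[rising] += self.amplitude * (t[rising] - t0) / self.upstroke_duration
        plateau = (t >= t1) & (t < t2)
        out[plateau] += self.amplitude
        if self.repolarization_duration > 0:
            falling = (t >= t2) & (t < t3)
            out[falling] += self.amplitude * (t3 - t[falling]) / self.repolarization_duration
        return out


def synth_action_potential(
    template: APTemplate,
    n_samples: int,
    sampling_rate: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Sample the template at ``sampling_rate`` Hz with Gaussian noise."""
    times = np.arange(n_samples) / sampling_rate * 1000.0
    trace = template.evaluate(times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=n_samples)
    return trace


def _surface_mesh_for(solid: AnalyticSolid, subdivisions: int = 3
                      ) -> trimesh.Trimesh:
    if solid.kind in ("sphere", "ellipsoid"):
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
        mesh.vertices = mesh.vertices * solid._semi_axes()
    else:
        mesh = trimesh.creation.box(extents=2 * solid._semi_axes())
        mesh = mesh.subdivide().subdivide()
    mesh.vertices = mesh.vertices @ solid.orientation.T + solid.center
    return mesh


def _pattern_activation_ms(
    pattern: str,
    centroids: np.ndarray,
    *,
    speed: float,
    focus: np.ndarray | None,
) -> np.ndarray:
    """Per-face activation time for plane_wave / paced_focus patterns."""
    if pattern == "plane_wave":
        z = centroids[:, 2]
        return (z - z.min()) / speed * 1000.0
    if pattern == "paced_focus":
        if focus is None:
            focus = centroids[np.argmin(centroids[:, 2])]
        d = np.linalg.norm(centroids - focus, axis=1)
        return d / speed * 1000.0
    raise PanomapError(f"unknown activation pattern {pattern!r}")


def synth_camera_movies(
    solid: AnalyticSolid,
    surface_pattern: str,
    cameras: dict[str, CameraModel],
    duration_ms: float,
    sampling_rate: float,
    seed: int = 0,
    *,
    speed: float = 1.0,
    focus: np.ndarray | None = None,
    template: APTemplate | None = None,
    spiral_frequency_hz: float = 7.0,
    noise_sd: float = 0.0,
    mesh_subdivisions: int = 3,
) -> dict:
    """Render a known surface activation pattern to every camera.

    A reference mesh of the solid carries the ground-truth signal: for
    ``plane_wave`` and ``paced_focus`` each face fires an
    :class:`APTemplate` delayed by its activation time (``speed`` in
    world units per second); for ``spiral`` each face carries a rotating
    sinusoid whose phase winds once around a point on the surface.  Each
    camera movie is ray-cast — a pixel sees the trace of the mesh face
    nearest to the visible surface point — with optional Gaussian noise.

    Returns a dict with per-camera ``movies``, the ground-truth
    ``mesh`` (a :class:`trimesh.Trimesh`), ``face_traces``,
    ``face_activation_ms`` (None for spiral) and the sample ``times_ms``.
    """
    rng = np.random.default_rng(seed)
    mesh = _surface_mesh_for(solid, mesh_subdivisions)
    centroids = mesh.triangles_center
    n_samples = int(round(duration_ms / 1000.0 * sampling_rate))
    times = np.arange(n_samples) / sampling_rate * 1000.0

    if template is None:
        template = APTemplate()

    if surface_pattern == "spiral":
        lam = np.arctan2(centroids[:, 1], centroids[:, 0])
        phi = np.arctan2(
            centroids[:, 2], np.hypot(centroids[:, 0], centroids[:, 1])
        )
        # phase winds once around a core on the equator at azimuth 0
        core_dir = np.array([1.0, 0.0, 0.0])
        spatial = np.arctan2(phi, lam)
        omega = 2 * np.pi * spiral_frequency_hz / 1000.0  # rad per ms
        face_traces = 0.5 * (
            1 + np.sin(omega * times[None, :] - spatial[:, None])
        )
        activation = None
    else:
        activation = _pattern_activation_ms(
            surface_pattern, centroids, speed=speed, focus=focus
        )
        base = template.evaluate(
            times[None, :] - activation[:, None] + template.upstroke_time
        )
        face_traces = base
    movies = {}
    for cam_id, cam in cameras.items():
        origin, dirs, grid_shape = _pixel_rays(cam, 1)
        hit, t = solid.ray_hits(origin, dirs)
        pts = origin + np.nan_to_num(t)[..., None] * dirs
        frames = np.zeros(grid_shape + (n_samples,), dtype=float)
        if hit.any():
            from scipy.spatial import cKDTree

            tree = cKDTree(centroids)
            _, face_idx = tree.query(pts[hit])
            frames[hit] = face_traces[face_idx]
        if noise_sd > 0:
            frames[hit] += rng.normal(0.0, noise_sd,
                                      size=(int(hit.sum()), n_samples))
        movies[cam_id] = OpticalMovie(
            frames=frames,
            sampling_rate=sampling_rate,
            camera_id=cam_id,
            mask=hit.astype(np.uint8),
        )
    return {
        "movies": movies,
        "mesh": mesh,
        "face_traces": face_traces,
        "face_activation_ms": activation,
        "times_ms": times,
        "template": template,
    }


def single_face_mesh(theta_deg: float, view_dir: np.ndarray):
    """One-triangle mesh whose outward normal makes ``theta_deg`` with
    ``view_dir`` — the fixture for sweeping the camera-assignment angle
    classification over controlled angles."""
    from .reconstruction import SurfaceMesh

    view_dir = np.asarray(view_dir, dtype=float)
    view_dir = view_dir / np.linalg.norm(view_dir)
    a = np.deg2rad(theta_deg)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(view_dir @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(view_dir, helper)
    e1 /= np.linalg.norm(e1)
    normal = np.cos(a) * view_dir + np.sin(a) * np.cross(e1, view_dir)
    u = e1
    v = np.cross(normal, u)
    verts = np.array([np.zeros(3), u, v])
    mesh = SurfaceMesh(verts, np.array([[0, 1, 2]]))
    if mesh.face_normals[0] @ normal < 0:
        mesh = SurfaceMesh(verts, np.array([[0, 2, 1]]))
    return mesh


def synth_spiral_phase_field(
    shape: tuple[int, int],
    center: tuple[float, float],
    chirality: int = 1,
) -> np.ndarray:
    """Wrapped phase field with a single singularity of given chirality.

    ``phi = chirality * atan2(y - cy, x - cx)`` wrapped to (-pi, pi];
    ``center`` is (x, y) = (column, row) and must lie inside the image.
    A core exactly on the integer pixel lattice produces phase
    differences of exactly pi across it, whose winding is ambiguous;
    place the core at half-integer coordinates (between pixels) for a
    clean topological charge.
    """
    h, w = shape
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise PanomapError("spiral center must lie inside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    phi = chirality * np.arctan2(yy - cy, xx - cx)
    return np.angle(np.exp(1j * phi))
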