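"""Unwrap per-face surface scalars into 2D map projections.

The closed epicardial mesh is parameterized in longitude/latitude about
the rotation (long) axis: each face centroid, translated to the mesh
centroid, gets an azimuth lambda in (-180, 180] degrees and an elevation
phi in [-90, 90] degrees.  Scalars are then rasterized into either a
Mercator projection (cylindrical conformal; meridian spacing preserved,
diverges at the poles so latitude is clamped) or a Hammer projection
(pseudo-azimuthal equal-area, so region sizes keep their true ratios).

Raster pixels sample the value of the nearest face on the unit sphere —
no interpolation, so isochrone discontinuities stay sharp and every
raster value equals some face value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import PanomapError
from .reconstruction import SurfaceMesh

__all__ = [
    "SphericalParam",
    "Raster2D",
    "spherical_parameterize",
    "project_mercator",
    "project_hammer",
    "hammer_forward",
    "mercator_y",
]


@dataclass
class SphericalParam:
    """Per-face longitude/latitude (degrees) about a chosen axis.

    Faces whose centroid lies on the axis have undefined longitude and
    are flagged in ``on_axis``.
    """

    lon_deg: np.ndarray
    lat_deg: np.ndarray
    axis: np.ndarray
    on_axis: np.ndarray


@dataclass
class Raster2D:
    """Rasterized map with an invertible pixel <-> (lon, lat) mapping.

    ``values`` is (ny, nx) with NaN for missing pixels; ``x`` and ``y``
    are the projection-plane coordinates of pixel centers; ``projection``
    is "mercator" or "hammer".
    """

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    projection: str
    lat_clamp_deg: float | None = None

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)


def spherical_parameterize(
    mesh: SurfaceMesh, axis: np.ndarray = (0.0, 0.0, 1.0)
) -> SphericalParam:
    """Longitude/latitude of each face centroid about ``axis``.

    Centroids are translated to the mesh centroid; latitude is the angle
    to the equatorial plane of the axis, longitude the azimuth about it
    (zero at an arbitrary but deterministic reference perpendicular).
    """
    axis = np.asarray(axis, dtype=float)
    na = np.linalg.norm(axis)
    if na == 0:
        raise PanomapError("axis must be nonzero")
    axis = axis / na
    # deterministic equatorial reference frame
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ axis) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = trial - (trial @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    c = mesh.face_centroids - mesh.to_trimesh().centroid
    za = c @ axis
    xa = c @ e1
    ya = c @ e2
    rho = np.hypot(xa, ya)
    on_axis = rho < 1e-12
    lat = np.degrees(np.arctan2(za, rho))
    lon = np.degrees(np.arctan2(ya, xa))
    lon[on_axis] = np.nan
    # wrap to (-180, 180]
    lon = np.where(lon <= -180.0, lon + 360.0, lon)
    return SphericalParam(lon_deg=lon, lat_deg=lat, axis=axis,
                          on_axis=on_axis)


def mercator_y(lat_deg: np.ndarray) -> np.ndarray:
    """Mercator ordinate ln tan(45 deg + phi/2) (input degrees)."""
    return np.log(np.tan(np.pi / 4 + np.deg2rad(lat_deg) / 2))


def hammer_forward(lon_deg: np.ndarray, lat_deg: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Hammer equal-area projection of (lon, lat) in degrees."""
    lam = np.deg2rad(lon_deg)
    phi = np.deg2rad(lat_deg)
    denom = np.sqrt(1 + np.cos(phi) * np.cos(lam / 2))
    x = 2 * np.sqrt(2) * np.cos(phi) * np.sin(lam / 2) / denom
    y = np.sqrt(2) * np.sin(phi) / denom
    return x, y


def _unit_dirs(lon_deg: np.ndarray, lat_deg: np.ndarray) -> np.ndarray:
    lam = np.deg2rad(lon_deg)
    phi = np.deg2rad(lat_deg)
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)],
        axis=-1,
    )


def _face_tree(param: SphericalParam) -> tuple[cKDTree, np.ndarray]:
    ok = ~param.on_axis
    dirs = _unit_dirs(param.lon_deg[ok], param.lat_deg[ok])
    return cKDTree(dirs), np.flatnonzero(ok)


def project_mercator(
    param: SphericalParam,
    values: np.ndarray,
    resolution: tuple[int, int] = (360, 181),
    lat_clamp_deg: float = 85.0,
) -> Raster2D:
    """Rasterize per-face values into a Mercator map.

    ``resolution`` is (nx, ny) pixels spanning longitude (-180, 180] and
    Mercator y between +-``mercator_y(lat_clamp_deg)`` (the projection
    diverges at the poles; the caps are reported missing rather than
    distorted).  Each pixel takes the value of the face nearest on the
    unit sphere.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    nx, ny = resolution
    tree, ok_idx = _face_tree(param)
    lon = (np.arange(nx) + 0.5) / nx * 360.0 - 180.0
    ymax = mercator_y(lat_clamp_deg)
    y = (np.arange(ny) + 0.5) / ny * 2 * ymax - ymax
    lat = np.degrees(2 * np.arctan(np.exp(y)) - np.pi / 2)
    lon_g, lat_g = np.meshgrid(lon, lat)
    dirs = _unit_dirs(lon_g.ravel(), lat_g.ravel())
    _, nn = tree.query(dirs)
    vals = values[ok_idx[nn]].reshape(ny, nx)
    return Raster2D(values=vals, x=lon, y=y, projection="mercator",
                    lat_clamp_deg=lat_clamp_deg)


def project_hammer(
    param: SphericalParam,
    values: np.ndarray,
    resolution: tuple[int, int] = (360, 181),
) -> Raster2D:
    """Rasterize per-face values into a Hammer (equal-area) map.

    The raster spans the Hammer ellipse ``(x/2*sqrt2, y/sqrt2)``; pixels
    outside the ellipse are missing.  Inside, the projection is inverted
    to (lon, lat) and the nearest face on the sphere supplies the value.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    nx, ny = resolution
    tree, ok_idx = _face_tree(param)
    x = (np.arange(nx) + 0.5) / nx * 4 * np.sqrt(2) - 2 * np.sqrt(2)
    y = (np.arange(ny) + 0.5) / ny * 2 * np.sqrt(2) - np.sqrt(2)
    xg, yg = np.meshgrid(x, y)
    # inverse Hammer
    z2 = 1 - (xg / 4) ** 2 - (yg / 2) ** 2
    inside = z2 > 0.5  # z > 1/sqrt(2) <=> inside the ellipse
    z = np.sqrt(np.where(inside, z2, np.nan))
    lam = 2 * np.arctan2(z * xg, 2 * (2 * z2 - 1))
    phi = np.arcsin(np.clip(z * yg, -1, 1))
    vals = np.full(xg.shape, np.nan)
    if inside.any():
        dirs = _unit_dirs(np.degrees(lam[inside]), np.degrees(phi[inside]))
        _, nn = tree.query(dirs)
        vals[inside] = values[ok_idx[nn]]
    return Raster2D(values=vals, x=x, y=y, projection="hammer")
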