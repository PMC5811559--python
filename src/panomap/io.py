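"""File formats: TIFF stacks, meshes, camera bundles, maps and rasters.

TIFF is the on-disk format for images and movies (multi-page stacks or
directories of numbered single-page files), PLY/OBJ/STL for meshes (PLY
optionally carrying a per-face scalar property), YAML for camera models
and the calibration cuboid, CSV for per-face maps and HDF5 for the
pipeline bundle.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import trimesh
import yaml

from .camera_geometry import CalibrationCuboid, CameraModel
from .errors import PanomapError
from .map_unwrap import Raster2D
from .reconstruction import SurfaceMesh

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_surface",
    "read_surface",
    "save_camera_bundle",
    "load_camera_bundle",
    "save_face_map_csv",
    "load_face_map_csv",
    "save_raster",
]


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def read_image_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Load a (T, H, W) image stack from a multi-page TIFF or a directory.

    Directories are read in lexicographic filename order.  The dtype is
    preserved; metadata records the source files.
    """
    path = Path(path)
    if not path.exists():
        raise PanomapError(f"no such image stack: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise PanomapError(f"no TIFF files in directory {path}")
        frames = []
        for f in files:
            arr = tifffile.imread(f)
            frames.append(arr)
        shapes = {a.shape for a in frames}
        if len(shapes) > 1:
            raise PanomapError(
                f"mixed frame shapes in {path}: {sorted(shapes)}"
            )
        stack = np.stack(frames)
        meta = {"files": [f.name for f in files]}
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        meta = {"files": [path.name]}
    return stack, meta


def write_image_stack(path: str | Path, frames: np.ndarray) -> None:
    """Write a (T, H, W) array as a multi-page TIFF (bit-exact round trip)."""
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    tifffile.imwrite(Path(path), frames)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

_MESH_FORMATS = ("ply", "obj", "stl")


def write_surface(
    mesh: SurfaceMesh,
    path: str | Path,
    fmt: str | None = None,
    face_scalars: np.ndarray | None = None,
) -> None:
    """Write a mesh as PLY (default), OBJ or STL.

    PLY files are ASCII and can carry one float scalar per face as a
    ``quality`` property (NaN for missing); other formats ignore
    ``face_scalars`` with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "ply"
    if fmt not in _MESH_FORMATS:
        raise PanomapError(
            f"unsupported mesh format {fmt!r}; supported: {_MESH_FORMATS}"
        )
    if fmt == "ply":
        _write_ply(mesh, path, face_scalars)
        return
    if face_scalars is not None:
        import warnings

        warnings.warn(f"{fmt} cannot carry per-face scalars; writing "
                      "geometry only")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    tm.export(path, file_type=fmt)


def _write_ply(mesh: SurfaceMesh, path: Path,
               face_scalars: np.ndarray | None) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_verts}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_cells}\n")
        fh.write("property list uchar int vertex_indices\n")
        if face_scalars is not None:
            fh.write("property double quality\n")
        fh.write("end_header\n")
        for v in mesh.vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        if face_scalars is not None:
            face_scalars = np.asarray(face_scalars, dtype=float).reshape(-1)
            if len(face_scalars) != mesh.n_cells:
                raise PanomapError("one scalar per face required")
            for f, q in zip(mesh.faces, face_scalars):
                fh.write(f"3 {f[0]} {f[1]} {f[2]} {float(q)!r}\n")
        else:
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_surface(path: str | Path
                 ) -> tuple[SurfaceMesh, np.ndarray | None]:
    """Load a mesh written by :func:`write_surface`.

    Returns (mesh, face_scalars) with scalars None when absent.
    """
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "ply":
        return _read_ply(path)
    tm = trimesh.load(path, force="mesh", process=False)
    return SurfaceMesh(np.array(tm.vertices), np.array(tm.faces)), None


def _read_ply(path: Path) -> tuple[SurfaceMesh, np.ndarray | None]:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise PanomapError(f"{path} is not a PLY file")
        n_verts = n_faces = 0
        props_face: list[str] = []
        element = None
        while True:
            line = fh.readline().strip()
            if line == "end_header":
                break
            parts = line.split()
            if parts[0] == "element":
                element = parts[1]
                if element == "vertex":
                    n_verts = int(parts[2])
                elif element == "face":
                    n_faces = int(parts[2])
            elif parts[0] == "property" and element == "face":
                props_face.append(parts[-1])
        verts = np.array(
            [[float(x) for x in fh.readline().split()[:3]]
             for _ in range(n_verts)]
        )
        faces = []
        scalars = [] if "quality" in props_face else None
        for _ in range(n_faces):
            parts = fh.readline().split()
            k = int(parts[0])
            faces.append([int(x) for x in parts[1:1 + k]])
            if scalars is not None:
                scalars.append(float(parts[1 + k]))
    mesh = SurfaceMesh(verts, np.array(faces))
    return mesh, None if scalars is None else np.array(scalars)


# ---------------------------------------------------------------------------
# cameras and cuboid
# ---------------------------------------------------------------------------


def save_camera_bundle(
    path: str | Path,
    cameras: dict[str, CameraModel],
    cuboid: CalibrationCuboid | None = None,
) -> None:
    """YAML bundle of named cameras (geometry + optical) and the cuboid."""
    doc = {"cameras": {k: c.to_dict() for k, c in cameras.items()}}
    if cuboid is not None:
        doc["cuboid"] = cuboid.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_camera_bundle(
    path: str | Path,
) -> tuple[dict[str, CameraModel], CalibrationCuboid | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cams = {k: CameraModel.from_dict(v) for k, v in doc["cameras"].items()}
    cub = (CalibrationCuboid.from_dict(doc["cuboid"])
           if "cuboid" in doc else None)
    return cams, cub


# ---------------------------------------------------------------------------
# maps and rasters
# ---------------------------------------------------------------------------


def save_face_map_csv(path: str | Path, values: np.ndarray,
                      kind: str = "value") -> None:
    """Per-face scalars as ``face_index,<kind>`` CSV (NaN for missing)."""
    values = np.asarray(values, dtype=float).reshape(-1)
    with open(path, "w") as fh:
        fh.write(f"face_index,{kind}\n")
        for i, v in enumerate(values):
            fh.write(f"{i},{'' if not np.isfinite(v) else repr(float(v))}\n")


def load_face_map_csv(path: str | Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            _, v = line.rstrip("\n").split(",", 1)
            rows.append(float(v) if v else np.nan)
    return np.array(rows)


def save_raster(path_stem: str | Path, raster: Raster2D,
                write_png: bool = True) -> None:
    """Raster grid as NPY plus a JSON sidecar; optional 16-bit PNG preview.

    The sidecar records the projection kind, axis samples and the value
    range used for PNG scaling so the image remains quantitative.
    """
    stem = Path(path_stem)
    np.save(stem.with_suffix(".npy"), raster.values)
    finite = raster.values[np.isfinite(raster.values)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    meta = {
        "projection": raster.projection,
        "x": raster.x.tolist(),
        "y": raster.y.tolist(),
        "lat_clamp_deg": raster.lat_clamp_deg,
        "vmin": vmin,
        "vmax": vmax,
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh)
    if write_png:
        rng = vmax - vmin if vmax > vmin else 1.0
        img = (raster.values - vmin) / rng
        img = np.where(np.isfinite(img), img, 0.0)
        iio.imwrite(stem.with_suffix(".png"),
                    (img * 65535).astype(np.uint16))
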