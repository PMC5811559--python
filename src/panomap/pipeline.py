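"""End-to-end pipeline: simulate -> calibrate -> carve -> project -> maps.

Each stage is an ordinary function taking and returning a plain state
dict; the command-line interface wraps the same functions around an
HDF5 state file, so scripted and interactive runs are identical.  The
full chain on synthetic data is:

1. ``simulate``    render calibration targets, rotation silhouettes and
                   optical movies for a known scene (seeded),
2. ``calibrate``   detect, label (with the two corner anchors a user
                   would supply) and solve every camera,
3. ``silhouette``  segment the rotation images into binary masks,
4. ``carve``       octree visual hull, marching cubes, Taubin smoothing,
5. ``condition``   normalize / bin / filter / detrend each movie and
                   build its blending weight mask,
6. ``project``     texture-map the movies onto the mesh,
7. ``analyze``     activation, APD and dominant-frequency maps,
8. ``unwrap``      Mercator and Hammer rasters of the activation map.

Deterministic given the seed; provenance (package version, config hash,
seed) is stored with the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .camera_geometry import (
    CalibrationCuboid,
    CameraModel,
    JunctionObservations,
    calibrate_camera,
    detect_junctions,
    label_junctions,
    reprojection_rmse,
)
from .ep_analysis import activation_times, apd_map, dominant_frequency_map
from .errors import ConfigError, PanomapError
from .io import save_camera_bundle, save_face_map_csv, save_raster, write_surface
from .map_unwrap import project_hammer, project_mercator, spherical_parameterize
from .reconstruction import (
    SurfaceMesh,
    carve_visual_hull,
    extract_surface,
    smooth_surface,
)
from .signal_conditioning import OpticalMovie, build_weight_mask, condition_movie
from .silhouette import SilhouetteStack, assemble_stack, segment_silhouette
from .surface_projection import assemble_projected_signals
from .synthetic_fixtures import (
    AnalyticSolid,
    APTemplate,
    make_ring_camera,
    render_calibration_target,
    render_rotation_silhouettes,
    synth_camera_movies,
)

log = logging.getLogger("panomap")

__all__ = ["PipelineConfig", "StudyBundle", "run_pipeline", "STAGES"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CuboidConfig(_Section):
    L: float = 1.0
    W: float = 1.0
    H: float = 2.0
    grid_spacing: float = 0.25


class SceneConfig(_Section):
    solid_kind: str = "ellipsoid"
    semi_axes: tuple[float, float, float] = (1.0, 1.0, 1.3)
    n_optical_cameras: int = 4
    camera_distance: float = 8.0
    optical_focal_px: float = 300.0
    optical_image_size: tuple[int, int] = (100, 100)
    geometry_focal_px: float = 300.0
    geometry_image_size: tuple[int, int] = (160, 160)
    calib_focal_px: float = 400.0
    calib_image_size: tuple[int, int] = (256, 256)
    calib_distance: float = 6.0


class SilhouetteConfig(_Section):
    start_angle_deg: float = 0.0
    step_deg: float = 5.0
    n_views: int = 72


class CarveConfig(_Section):
    max_depth: int = 6
    bounds_margin: float = 1.2
    smooth_iterations: int = 30
    smooth_lambda: float = 0.5
    smooth_mu: float = -0.53


class MovieConfig(_Section):
    pattern: str = "plane_wave"
    # paced ventricular conduction is ~0.5 m/s; in the inch-based world
    # units of the rabbit-scale rig that is ~20 units/s
    speed: float = 20.0
    duration_ms: float = 500.0
    sampling_rate: float  # Hz; acquisition-dependent, must be explicit
    noise_sd: float = 0.02


class ConditionConfig(_Section):
    bin_kernel: int = 3
    filter_order: int = 100
    passband: tuple[float, float] = (0.0, 100.0)
    drift_removal: bool = True


class AnalysisConfig(_Section):
    apd_level: float = 0.8
    df_band: tuple[float, float] = (0.5, 50.0)


class UnwrapConfig(_Section):
    resolution: tuple[int, int] = (256, 128)
    lat_clamp_deg: float = 85.0


class PipelineConfig(_Section):
    cuboid: CuboidConfig = CuboidConfig()
    scene: SceneConfig = SceneConfig()
    silhouette: SilhouetteConfig = SilhouetteConfig()
    carve: CarveConfig = CarveConfig()
    movie: MovieConfig
    condition: ConditionConfig = ConditionConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    unwrap: UnwrapConfig = UnwrapConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        try:
            return cls.model_validate(doc)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyBundle:
    """Paths + provenance tying together one pipeline run's products."""

    out_dir: Path
    provenance: dict
    artifacts: dict = field(default_factory=dict)
    state: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(state: dict, cfg: PipelineConfig, seed: int) -> dict:
    """Render every raw input for a known synthetic scene."""
    sc = cfg.scene
    cub = CalibrationCuboid(**cfg.cuboid.model_dump())
    solid = AnalyticSolid(sc.solid_kind, {"semi_axes": sc.semi_axes}
                          if sc.solid_kind != "sphere"
                          else {"radius": sc.semi_axes[0]})
    n = sc.n_optical_cameras
    # cameras sit diagonal to the cuboid faces so each calibration view
    # shows two gridded faces corner-on
    true_cams = {
        chr(ord("A") + i): make_ring_camera(
            45.0 + 360.0 * i / n, sc.camera_distance,
            f=sc.optical_focal_px, image_size=sc.optical_image_size,
        )
        for i in range(n)
    }
    geo_cam = make_ring_camera(45.0, sc.camera_distance,
                               f=sc.geometry_focal_px,
                               image_size=sc.geometry_image_size)

    calib = {}
    for name, cam in {**true_cams, "geometry": geo_cam}.items():
        # each camera photographs the cuboid from its experiment pose,
        # so the recovered extrinsics are directly usable downstream
        img, truth, mask = render_calibration_target(cam, cub)
        calib[name] = {"image": img, "mask": mask,
                       "truth_pixels": truth.pixels,
                       "truth_labels": truth.labels,
                       "true_camera": cam}

    sil = cfg.silhouette
    angles = sil.start_angle_deg + sil.step_deg * np.arange(sil.n_views)
    sil_stack = render_rotation_silhouettes(solid, geo_cam, angles)
    # grayscale rotation images for the segmentation stage: dark heart
    # on a bright backdrop
    sil_images = 1.0 - 0.85 * sil_stack.masks.astype(float)

    movie_cfg = cfg.movie
    sim = synth_camera_movies(
        solid, movie_cfg.pattern, true_cams,
        duration_ms=movie_cfg.duration_ms,
        sampling_rate=movie_cfg.sampling_rate,
        seed=seed,
        speed=movie_cfg.speed,
        noise_sd=movie_cfg.noise_sd,
    )
    state.update({
        "cuboid": cub,
        "solid": solid,
        "true_cameras": true_cams,
        "true_geometry_camera": geo_cam,
        "calibration": calib,
        "silhouette_images": sil_images,
        "silhouette_angles": angles,
        "movies_raw": sim["movies"],
        "truth_mesh": sim["mesh"],
        "truth_face_activation_ms": sim["face_activation_ms"],
        "seed": seed,
    })
    return state


def _camera_azimuth(cam: CameraModel) -> float:
    p = cam.position
    return float(np.degrees(np.arctan2(p[1], p[0])))


def stage_calibrate(state: dict, cfg: PipelineConfig) -> dict:
    """Detect, label and solve every camera from its calibration image."""
    cub: CalibrationCuboid = state["cuboid"]
    cameras = {}
    rmse = {}
    for name, c in state["calibration"].items():
        pts = detect_junctions(c["image"], c["mask"])
        truth_pix = c["truth_pixels"]
        truth_lab = c["truth_labels"]
        # the two corner anchors the interactive workflow asks the user
        # for: ground truth supplies what a user would click
        i_tl = int(np.argmin(truth_pix.sum(axis=1)))
        i_br = int(np.argmax(truth_pix.sum(axis=1)))
        anchors = [(truth_pix[i_tl], int(truth_lab[i_tl])),
                   (truth_pix[i_br], int(truth_lab[i_br]))]
        obs = label_junctions(pts, cub, anchors=anchors)
        cam = calibrate_camera(obs, cub,
                               image_size=c["true_camera"].image_size)
        cameras[name] = cam
        rmse[name] = reprojection_rmse(cam, obs, cub)
        log.info("calibrated %s: reprojection RMSE %.3f px", name, rmse[name])
    state["calibrated_cameras"] = cameras
    state["calibration_rmse_px"] = rmse
    return state


def stage_silhouette(state: dict, cfg: PipelineConfig) -> dict:
    """Segment rotation images and assemble the silhouette stack."""
    geo = state["calibrated_cameras"]["geometry"]
    masks = [segment_silhouette(img) for img in state["silhouette_images"]]
    sil = cfg.silhouette
    stack = assemble_stack(masks, sil.start_angle_deg, sil.step_deg, geo)
    state["silhouette_stack"] = stack
    return state


def stage_carve(state: dict, cfg: PipelineConfig) -> dict:
    """Visual-hull carve, isosurface extraction and smoothing."""
    cv = cfg.carve
    stack: SilhouetteStack = state["silhouette_stack"]
    volume = carve_visual_hull(stack, max_depth=cv.max_depth)
    mesh = extract_surface(volume)
    if cv.smooth_iterations > 0:
        mesh = smooth_surface(mesh, cv.smooth_iterations,
                              cv.smooth_lambda, cv.smooth_mu)
    log.info("carved mesh: %d faces, volume %.3f", mesh.n_cells,
             mesh.enclosed_volume)
    state["occupancy"] = volume
    state["mesh"] = mesh
    return state


def stage_condition(state: dict, cfg: PipelineConfig) -> dict:
    """Condition each camera movie and build its weight mask."""
    cc = cfg.condition
    conditioned = {}
    weights = {}
    for cid, movie in state["movies_raw"].items():
        out = condition_movie(
            movie,
            bin_kernel=cc.bin_kernel,
            filter_order=cc.filter_order,
            passband=cc.passband,
            drift_removal=cc.drift_removal,
        )
        conditioned[cid] = out
        weights[cid] = build_weight_mask(out.mask)
    state["movies"] = conditioned
    state["weight_masks"] = weights
    return state


def stage_project(state: dict, cfg: PipelineConfig) -> dict:
    """Texture-map conditioned movies onto the carved mesh."""
    cams = {k: v for k, v in state["calibrated_cameras"].items()
            if k != "geometry"}
    projected = assemble_projected_signals(
        state["mesh"], state["movies"], state["weight_masks"], cams
    )
    state["projected"] = projected
    return state


def stage_analyze(state: dict, cfg: PipelineConfig) -> dict:
    """Activation, APD and dominant-frequency maps."""
    an = cfg.analysis
    proj = state["projected"]
    act = activation_times(proj.signals, proj.sampling_rate)
    act.mesh = state["mesh"]
    apd = apd_map(proj.signals, proj.sampling_rate, act, level=an.apd_level)
    apd.mesh = state["mesh"]
    df = dominant_frequency_map(proj.signals, proj.sampling_rate,
                                band=an.df_band)
    df.mesh = state["mesh"]
    state["activation_map"] = act
    state["apd_map"] = apd
    state["df_map"] = df
    return state


def stage_unwrap(state: dict, cfg: PipelineConfig) -> dict:
    """Mercator and Hammer rasters of the activation map."""
    uw = cfg.unwrap
    param = spherical_parameterize(state["mesh"])
    act = state["activation_map"]
    state["raster_mercator"] = project_mercator(
        param, act.values, resolution=uw.resolution,
        lat_clamp_deg=uw.lat_clamp_deg,
    )
    state["raster_hammer"] = project_hammer(
        param, act.values, resolution=uw.resolution
    )
    state["spherical_param"] = param
    return state


STAGES = {
    "simulate": stage_simulate,
    "calibrate": stage_calibrate,
    "silhouette": stage_silhouette,
    "carve": stage_carve,
    "condition": stage_condition,
    "project": stage_project,
    "analyze": stage_analyze,
    "unwrap": stage_unwrap,
}

_STAGE_ORDER = list(STAGES)


def run_pipeline(
    config: PipelineConfig | dict | str | Path,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> StudyBundle:
    """Run the full chain and materialize the products.

    ``config`` may be a :class:`PipelineConfig`, a dict, or a YAML path.
    On stage failure the partial state is preserved on the bundle of the
    raised :class:`PanomapError`.
    """
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = config
    out = Path(out_dir) if out_dir is not None else Path("panomap_run")
    out.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    timings = {}
    for name in _STAGE_ORDER:
        t0 = time.time()
        try:
            if name == "simulate":
                state = stage_simulate(state, cfg, seed)
            else:
                state = STAGES[name](state, cfg)
        except Exception as exc:
            raise PanomapError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.time() - t0, 3)
        log.info("stage %-10s %6.2f s", name, timings[name])

    provenance = {
        "tool": "panomap",
        "version": __version__,
        "config_hash": cfg.content_hash(),
        "seed": seed,
        "timings_s": timings,
    }
    bundle = StudyBundle(out_dir=out, provenance=provenance, state=state)
    _materialize(bundle, cfg)
    return bundle


def _materialize(bundle: StudyBundle, cfg: PipelineConfig) -> None:
    out = bundle.out_dir
    st = bundle.state
    mesh: SurfaceMesh = st["mesh"]
    write_surface(mesh, out / "mesh.ply",
                  face_scalars=st["activation_map"].values)
    save_camera_bundle(
        out / "cameras.yaml",
        {**st["calibrated_cameras"]},
        st["cuboid"],
    )
    for kind, key in (("activation", "activation_map"),
                      ("apd", "apd_map"), ("df", "df_map")):
        save_face_map_csv(out / f"{kind}_map.csv", st[key].values, kind=kind)
    save_raster(out / "activation_mercator", st["raster_mercator"])
    save_raster(out / "activation_hammer", st["raster_hammer"])
    _write_bundle_h5(out / "bundle.h5", bundle, cfg)
    bundle.artifacts = {
        "mesh": out / "mesh.ply",
        "cameras": out / "cameras.yaml",
        "bundle": out / "bundle.h5",
        "activation_mercator": out / "activation_mercator.npy",
        "activation_hammer": out / "activation_hammer.npy",
    }


def _write_bundle_h5(path: Path, bundle: StudyBundle,
                     cfg: PipelineConfig) -> None:
    st = bundle.state
    with h5py.File(path, "w") as h5:
        h5.attrs["provenance"] = json.dumps(bundle.provenance)
        h5.attrs["config"] = json.dumps(cfg.model_dump(), default=str)
        g = h5.create_group("mesh")
        g.create_dataset("vertices", data=st["mesh"].vertices)
        g.create_dataset("faces", data=st["mesh"].faces)
        g = h5.create_group("maps")
        for key in ("activation_map", "apd_map", "df_map"):
            g.create_dataset(key, data=st[key].values)
        g = h5.create_group("projected")
        g.create_dataset("signals", data=st["projected"].signals)
        g.attrs["sampling_rate"] = st["projected"].sampling_rate
        klass = np.array([a.klass for a in st["projected"].assignments],
                         dtype=h5py.string_dtype())
        g.create_dataset("face_class", data=klass)
        g = h5.create_group("movies")
        for cid, mv in st["movies"].items():
            gg = g.create_group(cid)
            gg.create_dataset("frames", data=mv.frames, compression="gzip")
            gg.create_dataset("mask", data=mv.mask)
            gg.attrs["sampling_rate"] = mv.sampling_rate
        g = h5.create_group("occupancy")
        g.create_dataset("occupancy", data=st["occupancy"].occupancy,
                         compression="gzip")
        g.attrs["origin"] = st["occupancy"].origin
        g.attrs["resolution"] = st["occupancy"].resolution
        g = h5.create_group("rasters")
        g.create_dataset("mercator", data=st["raster_mercator"].values)
        g.create_dataset("hammer", data=st["raster_hammer"].values)
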