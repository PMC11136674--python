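"""Run configuration and the batch dataset generator.

A :class:`RunConfig` (typically loaded from YAML) fully specifies a
rendering run: bands, sources, materials, scene content, camera, transport
settings and outputs.  The schema is validated before any computation and
unknown keys are rejected.

:func:`run_batch` renders ``count`` images.  Image ``i`` derives its own
seed from ``(base seed, i)`` and, when configured, samples its own sun
angles from that seed -- so every image is independent of every other and
of the order in which images are rendered (the embarrassingly parallel
contract: a dataset is byte-identical no matter how rendering was
scheduled).  Each image writes its band PNGs, a lossless float raster
stack, label maps, YOLO boxes, and a metadata record; the batch writes a
manifest with content hashes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as pio
from .camera import (CameraIntrinsics, CameraPose, DistortionCoefficients,
                     render)
from .geometry import (Material, RadiationSource, Scene, build_ground,
                       import_mesh)
from .leafoptics import AbsorptionTables, LeafBiochemistry, prospect
from .plants import build_canopy, species_preset
from .spectra import Spectrum, WaveBand
from .transport import TransportConfig

log = logging.getLogger(__name__)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BandCfg(_Model):
    label: str
    lambda_min_nm: float
    lambda_max_nm: float
    longwave: bool = False


class SourceCfg(_Model):
    kind: str
    direction: Optional[list[float]] = None
    position: Optional[list[float]] = None
    normal: Optional[list[float]] = None
    radius: float = 0.0
    extent: tuple[float, float] = (0.0, 0.0)
    band_fluxes: dict[str, float] = Field(default_factory=dict)
    sky_temperature: Optional[float] = None
    spectrum_file: Optional[str] = None


class MaterialCfg(_Model):
    rho_file: Optional[str] = None
    tau_file: Optional[str] = None
    band_overrides: dict[str, tuple[float, float]] = Field(default_factory=dict)
    prospect: Optional[dict[str, float]] = None     # biochemistry -> spectra
    prospect_mode: Literal["D", "PRO"] = "D"


class GroundCfg(_Model):
    extent: tuple[float, float] = (4.0, 4.0)
    tiles: tuple[int, int] = (2, 2)
    material: str = "ground"
    temperature: Optional[float] = None


class PlantsCfg(_Model):
    species: str = "bean-like"
    rows: int = 2
    cols: int = 2
    spacing: float = 0.4
    overrides: dict = Field(default_factory=dict)


class MeshCfg(_Model):
    path: str
    material: str = "default"


class PoseCfg(_Model):
    position: list[float]
    view_direction: Optional[list[float]] = None
    look_at: Optional[list[float]] = None
    up: list[float] = Field(default_factory=lambda: [0.0, 0.0, 1.0])


class CameraCfg(_Model):
    hfov_deg: float = 54.0
    resolution: tuple[int, int] = (128, 128)
    lens_diameter: float = 0.0
    focal_plane_distance: float = 2.0
    sensor_width: float = 0.036
    samples_per_pixel: int = 8
    pose: PoseCfg
    response_files: dict[str, str] = Field(default_factory=dict)
    distortion: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)


class TransportCfg(_Model):
    rays_per_primitive_direct: int = 32
    rays_per_primitive_diffuse: int = 16
    max_scattering_iterations: int = 20
    residual_fraction_tol: float = 0.005
    default_temperature: Optional[float] = None


class VariationCfg(_Model):
    count: int = 1
    sun_zenith_deg_range: Optional[tuple[float, float]] = None
    sun_azimuth_deg_range: Optional[tuple[float, float]] = None


class OutputCfg(_Model):
    directory: str = "output"
    png_white_point: Optional[float] = None
    gamma: float = 2.2
    annotations: list[str] = Field(default_factory=lambda: ["plant_id"])
    box_key: Optional[str] = "plant_id"
    min_box_pixels: int = 4
    sky_radiance: dict[str, float] = Field(default_factory=dict)


class RunConfig(_Model):
    seed: int = 0
    bands: list[BandCfg]
    sources: list[SourceCfg]
    materials: dict[str, MaterialCfg] = Field(default_factory=dict)
    ground: Optional[GroundCfg] = None
    plants: Optional[PlantsCfg] = None
    meshes: list[MeshCfg] = Field(default_factory=list)
    camera: CameraCfg
    transport: TransportCfg = Field(default_factory=TransportCfg)
    variation: VariationCfg = Field(default_factory=VariationCfg)
    output: OutputCfg = Field(default_factory=OutputCfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# config -> domain objects


def _build_materials(cfg: RunConfig) -> dict[str, Material]:
    mats = {}
    tables = None
    for name, mc in cfg.materials.items():
        rho = Spectrum.from_text(mc.rho_file) if mc.rho_file else None
        tau = Spectrum.from_text(mc.tau_file) if mc.tau_file else None
        if mc.prospect is not None:
            if tables is None:
                tables = AbsorptionTables.synthetic_default()
            bio = LeafBiochemistry(**mc.prospect)
            rho, tau = prospect(bio, tables, mode=mc.prospect_mode)
        mats[name] = Material(name, rho_spectrum=rho, tau_spectrum=tau,
                              band_overrides=dict(mc.band_overrides))
    return mats


def _build_sources(cfg: RunConfig, rng: np.random.Generator
                   ) -> list[RadiationSource]:
    sources = []
    v = cfg.variation
    for sc in cfg.sources:
        direction = sc.direction
        if sc.kind in ("collimated_sun", "sun_sphere") and \
                v.sun_zenith_deg_range is not None:
            zen = np.deg2rad(rng.uniform(*v.sun_zenith_deg_range))
            azr = v.sun_azimuth_deg_range or (0.0, 360.0)
            az = np.deg2rad(rng.uniform(*azr))
            direction = [np.sin(zen) * np.cos(az), np.sin(zen) * np.sin(az),
                         np.cos(zen)]
        spectrum = (Spectrum.from_text(sc.spectrum_file)
                    if sc.spectrum_file else None)
        sources.append(RadiationSource(
            kind=sc.kind, direction=direction, position=sc.position,
            normal=sc.normal, radius=sc.radius, extent=sc.extent,
            band_fluxes=dict(sc.band_fluxes),
            sky_temperature=sc.sky_temperature,
            spectral_distribution=spectrum))
    return sources


def build_scene(cfg: RunConfig, image_seed: int,
                rng: np.random.Generator) -> Scene:
    mats = _build_materials(cfg)
    prims = []
    if cfg.ground is not None:
        data = {"plant_id": 0}
        if cfg.ground.temperature is not None:
            data["temperature"] = cfg.ground.temperature
        prims += build_ground(cfg.ground.extent, cfg.ground.tiles,
                              material=cfg.ground.material, data=data)
    uid = 1 + max((p.uid for p in prims), default=-1)
    if cfg.plants is not None:
        params = species_preset(cfg.plants.species, seed=image_seed,
                                **cfg.plants.overrides)
        prims += build_canopy(params, rows=cfg.plants.rows,
                              cols=cfg.plants.cols,
                              spacing=cfg.plants.spacing, uid_start=uid)
        uid = 1 + max(p.uid for p in prims)
    for mc in cfg.meshes:
        mesh_prims = import_mesh(mc.path, material=mc.material,
                                 uid_start=uid)
        prims += mesh_prims
        uid = 1 + max(p.uid for p in prims)
    return Scene(prims, mats, _build_sources(cfg, rng))


def _camera_objects(cfg: CameraCfg
                    ) -> tuple[CameraIntrinsics, CameraPose,
                               DistortionCoefficients]:
    responses = {label: Spectrum.from_text(path)
                 for label, path in cfg.response_files.items()}
    intr = CameraIntrinsics(
        hfov=np.deg2rad(cfg.hfov_deg), resolution=tuple(cfg.resolution),
        lens_diameter=cfg.lens_diameter,
        focal_plane_distance=cfg.focal_plane_distance,
        sensor_width=cfg.sensor_width,
        samples_per_pixel=cfg.samples_per_pixel, response=responses)
    p = cfg.pose
    view = p.view_direction
    if view is None:
        if p.look_at is None:
            raise ValueError("camera pose needs view_direction or look_at")
        view = (np.asarray(p.look_at, dtype=float)
                - np.asarray(p.position, dtype=float))
    pose = CameraPose(position=p.position, view_direction=view, up_hint=p.up)
    return intr, pose, DistortionCoefficients(*cfg.distortion)


def image_seed_for(base_seed: int, index: int) -> int:
    """Stable per-image seed derivation (independent of render order)."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
               % (2 ** 31))


def render_one(cfg: RunConfig, index: int) -> tuple[dict, "object"]:
    """Render image ``index`` of the batch; returns (metadata, product)."""
    seed = image_seed_for(cfg.seed, index)
    rng = np.random.default_rng(seed)
    scene = build_scene(cfg, seed, rng)
    bands = [WaveBand(b.label, b.lambda_min_nm, b.lambda_max_nm, b.longwave)
             for b in cfg.bands]
    intr, pose, dist = _camera_objects(cfg.camera)
    tc = TransportConfig(
        rays_per_primitive_direct=cfg.transport.rays_per_primitive_direct,
        rays_per_primitive_diffuse=cfg.transport.rays_per_primitive_diffuse,
        max_scattering_iterations=cfg.transport.max_scattering_iterations,
        residual_fraction_tol=cfg.transport.residual_fraction_tol,
        seed=seed, default_temperature=cfg.transport.default_temperature)
    product = render(scene, bands, intr, pose, tc,
                     sky_radiance=cfg.output.sky_radiance or None,
                     annotation_keys=tuple(cfg.output.annotations),
                     with_depth=True,
                     distortion=None if dist.is_identity else dist)
    sun = next((s for s in scene.sources
                if s.kind in ("collimated_sun", "sun_sphere")), None)
    meta = {
        "index": index, "seed": seed,
        "n_primitives": len(scene),
        "sun_direction": (None if sun is None
                          else [round(float(x), 9) for x in sun.direction]),
        "bands": [b.label for b in bands],
        "ledger": product.ledger,
    }
    return meta, product


def run_batch(cfg: RunConfig, out_dir=None, order=None) -> dict:
    """Render the whole batch; returns the manifest (also written to disk).

    ``order`` optionally permutes the rendering schedule -- outputs must be
    (and are) independent of it.
    """
    out = Path(out_dir if out_dir is not None else cfg.output.directory)
    out.mkdir(parents=True, exist_ok=True)
    indices = list(order) if order is not None else list(range(cfg.variation.count))
    if sorted(indices) != list(range(cfg.variation.count)):
        raise ValueError("order must be a permutation of the image indices")
    records = {}
    errors = {}
    for index in indices:
        try:
            meta, product = render_one(cfg, index)
            files = _write_image_products(cfg, out, index, meta, product)
            records[str(index)] = files
        except Exception as exc:            # partial failure: record and go on
            log.exception("image %d failed", index)
            errors[str(index)] = repr(exc)
    manifest = {
        "count": cfg.variation.count,
        "seed": cfg.seed,
        "images": {k: {f: pio.file_sha256(out / f) for f in sorted(v)}
                   for k, v in sorted(records.items())},
        "errors": errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    if errors:
        raise RuntimeError(f"{len(errors)} image(s) failed; see manifest")
    return manifest


def _write_image_products(cfg: RunConfig, out: Path, index: int, meta: dict,
                          product) -> list[str]:
    stem = f"img{index:05d}"
    files = []
    labels = sorted(product.band_images)
    stack = np.stack([product.band_images[k] for k in labels])
    pio.write_float_raster(stack, out / f"{stem}.bsq", band_labels=labels)
    files += [f"{stem}.bsq", f"{stem}.bsq.hdr.json"]
    wp = cfg.output.png_white_point or max(float(stack.max()), 1e-12)
    if len(labels) == 3:
        pio.write_band_image(stack, out / f"{stem}.png", white_point=wp,
                             gamma=cfg.output.gamma)
        files.append(f"{stem}.png")
    else:
        for i, lab in enumerate(labels):
            pio.write_band_image(stack[i], out / f"{stem}_{lab}.png",
                                 white_point=wp, gamma=cfg.output.gamma)
            files.append(f"{stem}_{lab}.png")
    ann = {k: v for k, v in product.label_maps.items()}
    if product.depth_map is not None:
        ann["depth_m"] = np.where(np.isfinite(product.depth_map),
                                  product.depth_map, -1.0)
    if product.thermal_map is not None:
        ann["thermal"] = product.thermal_map
    if ann:
        keys = sorted(ann)
        pio.write_float_raster(np.stack([ann[k] for k in keys]),
                               out / f"{stem}_labels.bsq", band_labels=keys,
                               units="mixed")
        files += [f"{stem}_labels.bsq", f"{stem}_labels.bsq.hdr.json"]
    if cfg.output.box_key and cfg.output.box_key in product.label_maps:
        boxes = pio.boxes_from_labels(product.label_maps[cfg.output.box_key],
                                      min_pixels=cfg.output.min_box_pixels)
        pio.write_yolo_boxes(boxes, out / f"{stem}.txt")
        files.append(f"{stem}.txt")
    (out / f"{stem}.json").write_text(json.dumps(meta, indent=1,
                                                 sort_keys=True))
    files.append(f"{stem}.json")
    return files
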