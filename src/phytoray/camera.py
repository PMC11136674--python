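"""Thin-lens camera: pixel rays, image formation, annotation, distortion.

The camera is specified by its horizontal field of view, resolution, lens
diameter, focal-plane distance, sensor size, and pose.  Three parallel
planes define the geometry: the image plane (physical sensor) a distance
``d = (sensor_width / 2) / tan(hfov / 2)`` behind the lens principal plane,
the lens plane, and the focal plane at the focusing distance in front.  A
pixel ray originates at a jitter-sampled point on the lens disk and passes
through the focal-plane conjugate of a jitter-sampled point inside the
pixel (found by projecting the pixel point through the lens centre).  With
``lens_diameter -> 0`` this degenerates to a pinhole camera and everything
is in focus.

Radiometric contract: a pixel value is the sample-averaged camera-weighted
scattered exitance (W m^-2) of the surface side each ray hits -- the
to-be-scattered camera buffer of the transport solver, accumulated over all
scattering iterations.  For an unobstructed Lambertian plate under a
collimated source this makes the pixel exactly ``rho_o * S * cos(theta)``.
Sky (miss) pixels read a configurable per-band sky radiance, default 0.

Annotation, depth, and thermal maps use a single deterministic ray per
pixel from the lens centre through the pixel centre; the nearest primitive
wins, with no blending between labels.

Lens distortion is applied as a forward pixel remap in centred pixel
coordinates (principal point at the image centre):

    du = u (p1 r^2 + p2 r^4) + 2 p3 u v + p4 (r^2 + 2 u^2)
    dv = v (p1 r^2 + p2 r^4) + 2 p4 u v + p3 (r^2 + 2 v^2)

with ``r^2 = u^2 + v^2``; destinations are rounded to the nearest pixel,
unfilled destinations take the background value (producing the
characteristic dark gaps at the border for barrel parameters), and
collisions resolve last-write in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import Scene, _unit
from .spectra import SIGMA_SB, Spectrum, WaveBand
from .transport import RadiationField, TransportConfig, run_transport


@dataclass
class CameraIntrinsics:
    hfov: float                               # radians
    resolution: tuple[int, int]               # (width_px, height_px)
    lens_diameter: float = 0.0                # m; 0 -> pinhole
    focal_plane_distance: float = 1.0         # m
    sensor_width: float = 0.036               # m
    sensor_height: Optional[float] = None     # m; default keeps pixel aspect
    samples_per_pixel: int = 16
    response: dict[str, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.hfov < np.pi:
            raise ValueError("hfov must lie in (0, pi)")
        if self.lens_diameter < 0 or self.focal_plane_distance <= 0:
            raise ValueError("lens_diameter >= 0 and focal distance > 0 required")
        if self.samples_per_pixel < 1:
            raise ValueError("samples_per_pixel must be >= 1")
        w, h = self.resolution
        if w < 1 or h < 1:
            raise ValueError("resolution must be positive")
        if self.sensor_height is None:
            self.sensor_height = self.sensor_width * h / w


@dataclass
class CameraPose:
    position: np.ndarray
    view_direction: np.ndarray
    up_hint: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.view_direction = _unit(self.view_direction)
        self.up_hint = _unit(self.up_hint)
        if abs(np.dot(self.view_direction, self.up_hint)) > 1 - 1e-9:
            raise ValueError("view direction and up hint are parallel")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(forward, right, up) orthonormal camera frame."""
        f = self.view_direction
        r = _unit(np.cross(f, self.up_hint))
        u = np.cross(r, f)
        return f, r, u


@dataclass
class DistortionCoefficients:
    """p1/p2 radial, p3/p4 tangential; centred-pixel-coordinate convention."""

    p1: float = 0.0
    p2: float = 0.0
    p3: float = 0.0
    p4: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.p1 == self.p2 == self.p3 == self.p4 == 0.0


@dataclass
class RenderedProduct:
    """Aligned multi-band images plus annotation products."""

    band_images: dict[str, np.ndarray]
    label_maps: dict[str, np.ndarray] = field(default_factory=dict)
    depth_map: Optional[np.ndarray] = None
    thermal_map: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)
    ledger: list = field(default_factory=list)


def image_plane_distance(intr: CameraIntrinsics) -> float:
    """Sensor-to-lens distance implied by sensor width and HFOV."""
    return (intr.sensor_width / 2.0) / np.tan(intr.hfov / 2.0)


def _pixel_image_coords(intr: CameraIntrinsics, px: np.ndarray, py: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Continuous pixel coordinates -> physical offsets on the image plane."""
    w, h = intr.resolution
    x = (px / w - 0.5) * intr.sensor_width
    y = (0.5 - py / h) * intr.sensor_height
    return x, y


def _rays_for_pixels(intr: CameraIntrinsics, pose: CameraPose,
                     px: np.ndarray, py: np.ndarray,
                     rng: Optional[np.random.Generator]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Thin-lens rays through continuous pixel positions (px, py).

    With ``rng=None`` origins sit at the lens centre (used for the
    deterministic annotation rays); otherwise origins are uniform samples on
    the lens disk.
    """
    f, r, u = pose.basis()
    d = image_plane_distance(intr)
    fd = intr.focal_plane_distance
    x, y = _pixel_image_coords(intr, px, py)
    scale = fd / d
    focal_pts = (pose.position + fd * f
                 + (x * scale)[:, None] * r + (y * scale)[:, None] * u)
    n = px.size
    if rng is None or intr.lens_diameter == 0.0:
        origins = np.broadcast_to(pose.position, (n, 3)).copy()
    else:
        rad = 0.5 * intr.lens_diameter * np.sqrt(rng.random(n))
        phi = 2 * np.pi * rng.random(n)
        origins = (pose.position + (rad * np.cos(phi))[:, None] * r
                   + (rad * np.sin(phi))[:, None] * u)
    dirs = focal_pts - origins
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return origins, dirs


def sample_pixel_rays(intr: CameraIntrinsics, pose: CameraPose,
                      pixel: tuple[int, int], n: int, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """``n`` jittered thin-lens rays for one pixel (col, row)."""
    col, row = pixel
    w, h = intr.resolution
    if not (0 <= col < w and 0 <= row < h):
        raise ValueError("pixel outside resolution")
    rng = np.random.default_rng(np.random.SeedSequence([seed, row * w + col]))
    px = col + rng.random(n)
    py = row + rng.random(n)
    return _rays_for_pixels(intr, pose, px, py, rng)


def _all_pixel_samples(intr: CameraIntrinsics, pose: CameraPose, seed: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Jittered rays for every pixel: arrays of shape (H*W*spp, 3)."""
    w, h = intr.resolution
    spp = intr.samples_per_pixel
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    px = np.repeat(cols.ravel(), spp) + rng.random(h * w * spp)
    py = np.repeat(rows.ravel(), spp) + rng.random(h * w * spp)
    return _rays_for_pixels(intr, pose, px, py, rng)


def _center_rays(intr: CameraIntrinsics, pose: CameraPose
                 ) -> tuple[np.ndarray, np.ndarray]:
    w, h = intr.resolution
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    px = cols.ravel() + 0.5
    py = rows.ravel() + 0.5
    return _rays_for_pixels(intr, pose, px, py, None)


def camera_pass(field_: RadiationField, hit_idx: np.ndarray,
                hit_side: np.ndarray, intr: CameraIntrinsics,
                images: dict[str, np.ndarray],
                sky_radiance: Optional[dict[str, float]] = None,
                first_iteration: bool = False) -> None:
    """Accumulate the current iteration's camera-weighted TBS buffers.

    ``hit_idx``/``hit_side`` are the precomputed intersections of the pixel
    sample rays (-1 for sky).  Sky radiance is added once, on the first
    iteration only.
    """
    w, h = intr.resolution
    spp = intr.samples_per_pixel
    hit = hit_idx >= 0
    for b, band in enumerate(field_.bands):
        vals = np.zeros(hit_idx.size)
        vals[hit] = field_.tbs_camera[hit_idx[hit], b, hit_side[hit]]
        if first_iteration and sky_radiance:
            vals[~hit] = sky_radiance.get(band.label, 0.0)
        images[band.label] += vals.reshape(h, w, spp).mean(axis=2)


def annotate(scene: Scene, intr: CameraIntrinsics, pose: CameraPose,
             data_key: str, background=0.0, missing="background"
             ) -> np.ndarray:
    """Per-pixel label map of a primitive datum via centre rays.

    The nearest primitive's ``data[data_key]`` is returned per pixel;
    misses (and, with ``missing='background'``, hits whose primitive lacks
    the key -- with a warning) take the ``background`` value.
    """
    import warnings

    w, h = intr.resolution
    O, D = _center_rays(intr, pose)
    idx, _, _ = scene.intersect(O, D)
    out = np.full(h * w, background, dtype=float)
    missing_count = 0
    for i in np.flatnonzero(idx >= 0):
        data = scene.primitives[idx[i]].data
        if data_key in data:
            out[i] = data[data_key]
        else:
            missing_count += 1
            if missing == "error":
                raise KeyError(
                    f"primitive uid={scene.primitives[idx[i]].uid} lacks "
                    f"data key {data_key!r}")
    if missing_count:
        warnings.warn(f"{missing_count} pixels hit primitives lacking "
                      f"{data_key!r}; set to background", stacklevel=2)
    return out.reshape(h, w)


def depth_image(scene: Scene, intr: CameraIntrinsics, pose: CameraPose
                ) -> np.ndarray:
    """Centre-ray distance from the lens centre to the hit point (m);
    +inf for sky pixels."""
    w, h = intr.resolution
    O, D = _center_rays(intr, pose)
    _, t, _ = scene.intersect(O, D)
    return t.reshape(h, w)


def thermal_image(scene: Scene, intr: CameraIntrinsics, pose: CameraPose,
                  mode: str = "temperature", background: float = 0.0,
                  default_temperature: Optional[float] = None) -> np.ndarray:
    """Centre-ray thermal map: primitive temperature (K) or emitted flux
    ``eps * sigma * T^4`` (W m^-2)."""
    if mode not in ("temperature", "emitted_flux"):
        raise ValueError("mode must be 'temperature' or 'emitted_flux'")
    w, h = intr.resolution
    O, D = _center_rays(intr, pose)
    idx, _, _ = scene.intersect(O, D)
    out = np.full(h * w, background, dtype=float)
    for i in np.flatnonzero(idx >= 0):
        p = scene.primitives[idx[i]]
        T = p.data.get("temperature", default_temperature)
        if T is None:
            continue
        out[i] = T if mode == "temperature" else p.emissivity * SIGMA_SB * T ** 4
    return out.reshape(h, w)


def apply_distortion(image: np.ndarray, coeffs: DistortionCoefficients,
                     background=0.0) -> np.ndarray:
    """Forward radial/tangential remap; identity for zero coefficients."""
    if coeffs.is_identity:
        return image.copy()
    h, w = image.shape[:2]
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    u = cols - (w - 1) / 2.0
    v = rows - (h - 1) / 2.0
    r2 = u ** 2 + v ** 2
    radial = coeffs.p1 * r2 + coeffs.p2 * r2 ** 2
    du = u * radial + 2 * coeffs.p3 * u * v + coeffs.p4 * (r2 + 2 * u ** 2)
    dv = v * radial + 2 * coeffs.p4 * u * v + coeffs.p3 * (r2 + 2 * v ** 2)
    dest_c = np.rint(u + du + (w - 1) / 2.0).astype(np.int64)
    dest_r = np.rint(v + dv + (h - 1) / 2.0).astype(np.int64)
    ok = (dest_c >= 0) & (dest_c < w) & (dest_r >= 0) & (dest_r < h)
    out = np.full_like(image, background)
    flat_dest = (dest_r[ok] * w + dest_c[ok])
    vals = image[rows[ok], cols[ok]]
    # last write in row-major source order wins on collisions
    rev_first = np.unique(flat_dest[::-1], return_index=True)
    out.reshape(h * w, *image.shape[2:])[rev_first[0]] = \
        vals[::-1][rev_first[1]]
    return out


def distortion_shift(u: float, v: float, coeffs: DistortionCoefficients
                     ) -> tuple[float, float]:
    """(du, dv) displacement of a centred pixel coordinate -- the remap's
    defining formula, exposed for verification."""
    r2 = u ** 2 + v ** 2
    radial = coeffs.p1 * r2 + coeffs.p2 * r2 ** 2
    du = u * radial + 2 * coeffs.p3 * u * v + coeffs.p4 * (r2 + 2 * u ** 2)
    dv = v * radial + 2 * coeffs.p4 * u * v + coeffs.p3 * (r2 + 2 * v ** 2)
    return du, dv


def render(scene: Scene, bands: list[WaveBand], intr: CameraIntrinsics,
           pose: CameraPose, cfg: TransportConfig,
           sky_radiance: Optional[dict[str, float]] = None,
           annotation_keys: tuple[str, ...] = (),
           thermal_mode: str = "temperature",
           with_depth: bool = False,
           distortion: Optional[DistortionCoefficients] = None
           ) -> RenderedProduct:
    """Full pipeline: transport solve + camera accumulation + annotation.

    Pixel-sample intersections are computed once and re-used across
    scattering iterations, so the image accumulates every scattering order
    of the camera-weighted buffers.
    """
    from .transport import compute_band_properties

    ext = [s for s in scene.sources if s.is_external]
    S = ext[0].spectral_distribution if ext else None
    props = compute_band_properties(scene, bands, S, intr.response)

    O, D = _all_pixel_samples(intr, pose, cfg.seed)
    hit_idx, _, hit_side = scene.intersect(O, D)
    w, h = intr.resolution
    images = {b.label: np.zeros((h, w)) for b in bands}

    def on_iteration(field_, iteration):
        camera_pass(field_, hit_idx, hit_side, intr, images, sky_radiance,
                    first_iteration=(iteration == 0))

    field_, ledger = run_transport(scene, bands, cfg, props=props,
                                   on_iteration=on_iteration)

    # direct thermal emission seen by the camera in longwave bands
    lw = [b for b in bands if b.longwave]
    if lw:
        hit = hit_idx >= 0
        emit = np.zeros(hit_idx.size)
        for i in np.flatnonzero(hit):
            p = scene.primitives[hit_idx[i]]
            T = p.data.get("temperature", cfg.default_temperature)
            if T is not None:
                emit[i] = p.emissivity * SIGMA_SB * T ** 4
        spp = intr.samples_per_pixel
        for band in lw:
            images[band.label] += emit.reshape(h, w, spp).mean(axis=2)

    labels = {key: annotate(scene, intr, pose, key) for key in annotation_keys}
    depth = depth_image(scene, intr, pose) if with_depth else None
    thermal = None
    if any(("temperature" in p.data) for p in scene.primitives) \
            or cfg.default_temperature is not None:
        thermal = thermal_image(scene, intr, pose, mode=thermal_mode,
                                default_temperature=cfg.default_temperature)
    if distortion is not None and not distortion.is_identity:
        images = {k: apply_distortion(v, distortion) for k, v in images.items()}
        labels = {k: apply_distortion(v, distortion) for k, v in labels.items()}
    return RenderedProduct(
        band_images=images, label_maps=labels, depth_map=depth,
        thermal_map=thermal,
        metadata={"seed": cfg.seed, "resolution": [w, h],
                  "bands": [b.label for b in bands]},
        ledger=ledger)
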