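"""Reverse Monte-Carlo radiation transport over planar-primitive scenes.

The solver launches rays *from* primitive surfaces toward the radiation
sources ("reverse" tracing), which guarantees every element is sampled no
matter how small or skewed it is.  Per primitive, per band, and per side it
keeps an energy ledger of incident and absorbed flux plus two families of
"to-be-scattered" (TBS) buffers: one weighted by the band surface
properties (rho, tau) that drives object-to-object scattering, and one
weighted by the camera properties (rho_o, tau_o) that a camera pass
queries.  Reflected energy re-enters the scene from the incident side,
transmitted energy from the opposite side; both are re-emitted Lambertian
(specular reflection is neglected).  All bands share each geometric ray.

Scattering proceeds iteratively: each iteration redistributes the TBS
energy of every primitive side through cosine-weighted hemispherical rays,
zeroes the old buffers, and refills fresh ones on the receiving primitives,
until the residual buffered energy falls below a configured fraction of the
injected energy.  Thermal emission enters the same machinery: each side
emits ``eps * sigma * T^4`` into the longwave band(s) as to-be-scattered
energy.

One approximation is inherited from the band-property precomputation: the
spectral distribution of scattered radiation is always taken to be the
source spectrum ``S_lambda``, which can differ from the true spectral flux
after multiple scattering.  This is a documented compromise in favour of
the reverse-tracing approach, not a defect to be fixed here.

Randomness uses one counter-based (Philox) stream per (pass, iteration,
primitive uid), so results are independent of primitive traversal order and
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import INTERSECT_EPS, Scene
from .spectra import (SIGMA_SB, Spectrum, WaveBand, band_camera_props,
                      stefan_boltzmann_flux)

log = logging.getLogger(__name__)

_PASS_IDS = {"direct": 1, "diffuse": 2, "emission": 3, "scatter": 4}


def _prim_rng(seed: int, pass_name: str, iteration: int, uid: int
              ) -> np.random.Generator:
    """Counter-based stream: independent of primitive traversal order."""
    key = np.array([(seed * 1009 + _PASS_IDS[pass_name]) * 100003 + iteration,
                    uid], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


@dataclass
class TransportConfig:
    rays_per_primitive_direct: int = 32
    rays_per_primitive_diffuse: int = 16
    max_scattering_iterations: int = 20
    residual_fraction_tol: float = 0.005
    seed: int = 0
    default_temperature: float | None = None   # K, used when a primitive
    # carries no 'temperature' datum during an emission pass

    def __post_init__(self) -> None:
        if self.rays_per_primitive_direct < 1 or self.rays_per_primitive_diffuse < 1:
            raise ValueError("ray counts must be >= 1")
        if self.max_scattering_iterations < 0:
            raise ValueError("iteration count must be >= 0")
        if not 0.0 < self.residual_fraction_tol < 1.0:
            raise ValueError("residual tolerance must lie in (0, 1)")


@dataclass
class BandPropertySet:
    """Per-primitive, per-band surface properties (M, B) arrays."""

    bands: list[WaveBand]
    rho: np.ndarray
    tau: np.ndarray
    rho_o: np.ndarray
    tau_o: np.ndarray


def compute_band_properties(scene: Scene, bands: list[WaveBand],
                            source_spectrum: Spectrum | None = None,
                            camera_response: dict[str, Spectrum] | None = None
                            ) -> BandPropertySet:
    """Integrate material spectra into per-band (rho, tau, rho_o, tau_o).

    ``source_spectrum`` is the weighting S_lambda (flat if None);
    ``camera_response`` maps band label to a response spectrum C_lambda
    (unit response where missing).  Longwave bands take rho = 1 - emissivity
    and tau = 0 (Kirchhoff's law) regardless of material spectra.
    """
    if source_spectrum is None:
        source_spectrum = Spectrum.constant(1.0)
    camera_response = camera_response or {}
    M, B = len(scene.primitives), len(bands)
    rho = np.zeros((M, B)); tau = np.zeros((M, B))
    rho_o = np.zeros((M, B)); tau_o = np.zeros((M, B))
    cache: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for m, p in enumerate(scene.primitives):
        for b, band in enumerate(bands):
            if band.longwave:
                rho[m, b] = 1.0 - p.emissivity
                rho_o[m, b] = rho[m, b]
                continue
            key = (p.material_front, band.label)
            if key not in cache:
                mat = scene.materials.get(p.material_front)
                if mat is None:
                    raise KeyError(f"material {p.material_front!r} not in scene")
                if band.label in mat.band_overrides:
                    r, t = mat.band_overrides[band.label]
                    C = camera_response.get(band.label)
                    if C is None:
                        ro, to = r, t
                    else:
                        one = Spectrum.constant(1.0)
                        cw, _ = band_camera_props(one, one, C, source_spectrum, band)
                        ro, to = r * cw, t * cw
                else:
                    rs = mat.rho_spectrum or Spectrum.constant(0.0)
                    ts = mat.tau_spectrum or Spectrum.constant(0.0)
                    r, t = band_camera_props(rs, ts, None, source_spectrum, band)
                    ro, to = band_camera_props(rs, ts,
                                               camera_response.get(band.label),
                                               source_spectrum, band)
                cache[key] = (r, t, ro, to)
            rho[m, b], tau[m, b], rho_o[m, b], tau_o[m, b] = cache[key]
    return BandPropertySet(list(bands), rho, tau, rho_o, tau_o)


@dataclass
class RadiationField:
    """Per-primitive / per-band / per-side (front=0, back=1) energy ledger.

    Fluxes are W m^-2 of primitive area; ``injected``/``escaped``/
    ``absorbed_energy`` are per-band totals in watts.
    """

    n_primitives: int
    bands: list[WaveBand]
    areas: np.ndarray                        # (M,)
    incident: np.ndarray = field(init=False)
    absorbed: np.ndarray = field(init=False)
    tbs_band: np.ndarray = field(init=False)
    tbs_camera: np.ndarray = field(init=False)
    injected: np.ndarray = field(init=False)   # (B,) W entering the ledger
    escaped: np.ndarray = field(init=False)    # (B,) W lost to the sky

    def __post_init__(self) -> None:
        M, B = self.n_primitives, len(self.bands)
        self.incident = np.zeros((M, B, 2))
        self.absorbed = np.zeros((M, B, 2))
        self.tbs_band = np.zeros((M, B, 2))
        self.tbs_camera = np.zeros((M, B, 2))
        self.injected = np.zeros(B)
        self.escaped = np.zeros(B)

    def residual_energy(self) -> np.ndarray:
        """Energy (W) still waiting in the band-weighted TBS buffers."""
        return (self.tbs_band * self.areas[:, None, None]).sum(axis=(0, 2))

    def absorbed_energy(self) -> np.ndarray:
        return (self.absorbed * self.areas[:, None, None]).sum(axis=(0, 2))

    def ledger_row(self) -> dict[str, float]:
        return {
            "injected_w": float(self.injected.sum()),
            "absorbed_w": float(self.absorbed_energy().sum()),
            "escaped_w": float(self.escaped.sum()),
            "residual_w": float(self.residual_energy().sum()),
        }


def _deposit(field_: RadiationField, props: BandPropertySet,
             inc: np.ndarray) -> None:
    """Split incident flux (M,B,2) into absorbed and the two TBS families."""
    field_.incident += inc
    absorb = (1.0 - props.rho - props.tau)[:, :, None] * inc
    field_.absorbed += absorb
    r = props.rho[:, :, None]
    t = props.tau[:, :, None]
    ro = props.rho_o[:, :, None]
    to = props.tau_o[:, :, None]
    # reflected energy leaves the incident side, transmitted the opposite one
    field_.tbs_band[:, :, 0] += (r * inc)[:, :, 0] + (t * inc)[:, :, 1]
    field_.tbs_band[:, :, 1] += (r * inc)[:, :, 1] + (t * inc)[:, :, 0]
    field_.tbs_camera[:, :, 0] += (ro * inc)[:, :, 0] + (to * inc)[:, :, 1]
    field_.tbs_camera[:, :, 1] += (ro * inc)[:, :, 1] + (to * inc)[:, :, 0]


def _cosine_dirs(normal: np.ndarray, n: int, rng: np.random.Generator
                 ) -> np.ndarray:
    """Cosine-weighted directions about a unit normal."""
    u1 = rng.random(n)
    u2 = rng.random(n)
    r = np.sqrt(u1)
    phi = 2 * np.pi * u2
    local = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                             np.sqrt(1.0 - u1)])
    # orthonormal frame around the normal
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 \
        else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return local @ np.vstack([t1, t2, normal])


def _band_flux_vector(source, bands: list[WaveBand]) -> np.ndarray:
    out = np.zeros(len(bands))
    for b, band in enumerate(bands):
        if source.kind == "longwave_sky":
            if band.longwave:
                out[b] = SIGMA_SB * source.sky_temperature ** 4
        else:
            out[b] = source.band_fluxes.get(band.label, 0.0)
    return out


# ---------------------------------------------------------------------------
# passes


def direct_pass(scene: Scene, cfg: TransportConfig, props: BandPropertySet,
                field_: RadiationField) -> None:
    """Sample external sources from every primitive surface."""
    bands = props.bands
    external = [s for s in scene.sources if s.is_external]
    M = len(scene.primitives)
    nrays = cfg.rays_per_primitive_direct
    for source in external:
        Sb = _band_flux_vector(source, bands)
        if not Sb.any():
            continue
        inc = np.zeros((M, len(bands), 2))
        if source.kind in ("collimated_sun", "sun_sphere"):
            origins = np.empty((M * nrays, 3))
            dirs = np.empty((M * nrays, 3))
            for m, p in enumerate(scene.primitives):
                rng = _prim_rng(cfg.seed, "direct", 0, p.uid)
                pts = scene.sample_points(m, nrays, rng)
                if source.kind == "collimated_sun":
                    d = np.broadcast_to(source.direction, (nrays, 3))
                else:
                    d = _cone_dirs(source.direction,
                                   np.deg2rad(0.266), nrays, rng)
                origins[m * nrays:(m + 1) * nrays] = pts
                dirs[m * nrays:(m + 1) * nrays] = d
            idx, _, _ = scene.intersect(origins, dirs)
            visible = (idx < 0).reshape(M, nrays)
            normals = np.array([p.normal for p in scene.primitives])
            cosf = np.einsum("mj,mrj->mr", normals,
                             dirs.reshape(M, nrays, 3))
            w_front = (np.maximum(cosf, 0.0) * visible).mean(axis=1)
            w_back = (np.maximum(-cosf, 0.0) * visible).mean(axis=1)
            inc[:, :, 0] = w_front[:, None] * Sb[None, :]
            inc[:, :, 1] = w_back[:, None] * Sb[None, :]
        elif source.kind in ("sphere", "disk", "rectangle"):
            inc = _terrestrial_source_pass(scene, cfg, source, Sb, nrays)
        else:  # pragma: no cover - validated in RadiationSource
            raise ValueError(f"unknown external source kind {source.kind!r}")
        _deposit(field_, props, inc)
        field_.injected += (inc.sum(axis=2) *
                            field_.areas[:, None]).sum(axis=0)


def _cone_dirs(axis: np.ndarray, half_angle: float, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Uniform directions within a cone about ``axis``."""
    u = rng.random(n)
    cos_t = 1.0 - u * (1.0 - np.cos(half_angle))
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    phi = 2 * np.pi * rng.random(n)
    local = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    a = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(axis, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)
    return local @ np.vstack([t1, t2, axis])


def _terrestrial_source_pass(scene: Scene, cfg: TransportConfig, source,
                             Sb: np.ndarray, nrays: int) -> np.ndarray:
    """Irradiance from a finite terrestrial source by point-pair sampling.

    ``Sb`` holds the total emitted power per band (W).  Spheres are sampled
    as isotropic point emitters distributed over the sphere surface; planar
    sources as cosine emitters over their area.
    """
    M = len(scene.primitives)
    B = Sb.size
    inc = np.zeros((M, B, 2))
    normals = np.array([p.normal for p in scene.primitives])
    for m, p in enumerate(scene.primitives):
        rng = _prim_rng(cfg.seed, "direct", 1, p.uid)
        pts = scene.sample_points(m, nrays, rng)
        if source.kind == "sphere":
            sp = _sphere_points(source.position, source.radius, nrays, rng)
            geom = 1.0 / (4.0 * np.pi)
            cos_s = np.ones(nrays)
        else:
            sp, src_n = _planar_source_points(source, nrays, rng)
            vec0 = pts - sp
            cos_s = np.einsum("j,rj->r", src_n, vec0)
            cos_s = np.maximum(cos_s, 0.0)   # emits from the normal side only
            geom = 1.0 / np.pi
        vec = sp - pts
        dist = np.linalg.norm(vec, axis=1)
        dvec = vec / dist[:, None]
        if source.kind != "sphere":
            cos_s = cos_s / dist             # normalise the projection
        cos_r = dvec @ normals[m]
        idx, t, _ = scene.intersect(pts, dvec)
        blocked = (idx >= 0) & (t < dist * (1 - 1e-9))
        w = np.where(blocked, 0.0, geom * cos_s / dist ** 2)
        front = (np.maximum(cos_r, 0.0) * w).mean()
        back = (np.maximum(-cos_r, 0.0) * w).mean()
        inc[m, :, 0] = front * Sb
        inc[m, :, 1] = back * Sb
    return inc


def _sphere_points(center, radius, n, rng):
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return np.asarray(center) + radius * d


def _planar_source_points(source, n, rng):
    nrm = source.normal
    a = np.array([1.0, 0.0, 0.0]) if abs(nrm[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(nrm, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(nrm, t1)
    if source.kind == "disk":
        r = source.radius * np.sqrt(rng.random(n))
        phi = 2 * np.pi * rng.random(n)
        pts = source.position + r[:, None] * (np.cos(phi)[:, None] * t1
                                              + np.sin(phi)[:, None] * t2)
    else:
        w, h = source.extent
        u = (rng.random(n) - 0.5) * w
        v = (rng.random(n) - 0.5) * h
        pts = source.position + u[:, None] * t1 + v[:, None] * t2
    return pts, nrm


def diffuse_pass(scene: Scene, cfg: TransportConfig, props: BandPropertySet,
                 field_: RadiationField) -> None:
    """Hemispherical sampling of sky sources (shortwave diffuse + longwave).

    Rays that escape the scene collect the sky flux; rays that hit
    primitives collect nothing here (inter-object scattering is handled by
    the iterative machinery).
    """
    bands = props.bands
    sky = [s for s in scene.sources if not s.is_external]
    if not sky:
        return
    Db = np.zeros(len(bands))
    for s in sky:
        Db += _band_flux_vector(s, bands)
    if not Db.any():
        return
    M = len(scene.primitives)
    nrays = cfg.rays_per_primitive_diffuse
    origins = np.empty((M * 2 * nrays, 3))
    dirs = np.empty((M * 2 * nrays, 3))
    normals = np.array([p.normal for p in scene.primitives])
    for m, p in enumerate(scene.primitives):
        rng = _prim_rng(cfg.seed, "diffuse", 0, p.uid)
        for side in (0, 1):
            pts = scene.sample_points(m, nrays, rng)
            nrm = normals[m] if side == 0 else -normals[m]
            d = _cosine_dirs(nrm, nrays, rng)
            lo = (m * 2 + side) * nrays
            origins[lo:lo + nrays] = pts + INTERSECT_EPS * nrm[None, :]
            dirs[lo:lo + nrays] = d
    idx, _, _ = scene.intersect(origins, dirs)
    esc = (idx < 0).reshape(M, 2, nrays).mean(axis=2)
    inc = np.transpose(esc[:, :, None] * Db[None, None, :], (0, 2, 1))
    _deposit(field_, props, inc)
    field_.injected += (inc.sum(axis=2) * field_.areas[:, None]).sum(axis=0)


def emission_pass(scene: Scene, cfg: TransportConfig, props: BandPropertySet,
                  field_: RadiationField) -> None:
    """Load thermal emission into the longwave TBS buffers.

    Each primitive side emits ``eps * sigma * T^4``; the energy then takes
    part in the ordinary scattering iterations, giving self-consistent
    longwave exchange.  Raises if a primitive lacks a temperature and no
    default is configured.
    """
    lw = [b for b, band in enumerate(props.bands) if band.longwave]
    if not lw:
        return
    M = len(scene.primitives)
    emitted = np.zeros((M, len(props.bands), 2))
    for m, p in enumerate(scene.primitives):
        T = p.data.get("temperature", cfg.default_temperature)
        if T is None:
            raise ValueError(
                f"primitive uid={p.uid} has no 'temperature' datum and no "
                "default_temperature is configured")
        e = stefan_boltzmann_flux(T, p.emissivity)
        for b in lw:
            emitted[m, b, :] = e
    field_.tbs_band += emitted
    # emission is not camera-weighted scattering; cameras add eps*sigma*T^4
    # of the hit primitive directly in thermal mode
    field_.injected += (emitted.sum(axis=2) *
                        field_.areas[:, None]).sum(axis=0)


def scattering_iteration(scene: Scene, cfg: TransportConfig,
                         props: BandPropertySet, field_: RadiationField,
                         iteration: int) -> float:
    """Redistribute all TBS energy once; returns the new residual (W).

    Every primitive side with buffered energy re-emits it through
    cosine-weighted (Lambertian) hemispherical rays; receiving primitives
    accumulate absorbed flux and refill fresh buffers; the old buffers are
    zeroed.  All bands ride each geometric ray simultaneously.
    """
    M = len(scene.primitives)
    B = len(props.bands)
    old = field_.tbs_band.copy()
    field_.tbs_band[:] = 0.0
    field_.tbs_camera[:] = 0.0
    areas = field_.areas
    active = np.nonzero(old.sum(axis=1).T)   # (side, prim) pairs with energy
    sides, prims = active
    if prims.size == 0:
        return 0.0
    n = cfg.rays_per_primitive_diffuse
    normals = np.array([p.normal for p in scene.primitives])
    origins = np.empty((prims.size * n, 3))
    dirs = np.empty((prims.size * n, 3))
    energies = np.empty((prims.size * n, B))
    for j, (m, side) in enumerate(zip(prims, sides)):
        p = scene.primitives[m]
        rng = _prim_rng(cfg.seed, "scatter", iteration, p.uid * 2 + side)
        pts = scene.sample_points(m, n, rng)
        nrm = normals[m] if side == 0 else -normals[m]
        d = _cosine_dirs(nrm, n, rng)
        origins[j * n:(j + 1) * n] = pts + INTERSECT_EPS * nrm[None, :]
        dirs[j * n:(j + 1) * n] = d
        energies[j * n:(j + 1) * n] = old[m, :, side] * areas[m] / n
    idx, _, side_hit = scene.intersect(origins, dirs)
    hit = idx >= 0
    field_.escaped += energies[~hit].sum(axis=0)
    if hit.any():
        inc = np.zeros((M, B, 2))
        contrib = energies[hit] / areas[idx[hit], None]
        np.add.at(inc, (idx[hit], slice(None), side_hit[hit]), contrib)
        _deposit(field_, props, inc)
    return float(field_.residual_energy().sum())


def run_transport(scene: Scene, bands: list[WaveBand], cfg: TransportConfig,
                  props: BandPropertySet | None = None,
                  camera_response: dict[str, Spectrum] | None = None,
                  on_iteration=None) -> tuple[RadiationField, list[dict]]:
    """Full transport solve: direct + diffuse + emission, then scattering
    iterations until the residual TBS energy drops below
    ``residual_fraction_tol`` of the injected energy.

    ``on_iteration(field, iteration)`` is invoked after the initial passes
    (iteration 0) and after each scattering iteration, while the
    camera-weighted TBS buffers of that iteration are still live -- this is
    where a camera pass accumulates its image.

    Returns the final field and a per-iteration energy-ledger table.
    """
    if props is None:
        ext = [s for s in scene.sources if s.is_external]
        S = ext[0].spectral_distribution if ext else None
        props = compute_band_properties(scene, bands, S, camera_response)
    areas = np.array([p.area for p in scene.primitives])
    field_ = RadiationField(len(scene.primitives), list(bands), areas)
    direct_pass(scene, cfg, props, field_)
    diffuse_pass(scene, cfg, props, field_)
    emission_pass(scene, cfg, props, field_)
    ledger = [dict(iteration=0, **field_.ledger_row())]
    if on_iteration is not None:
        on_iteration(field_, 0)
    injected = field_.injected.sum()
    residual = field_.residual_energy().sum()
    it = 0
    while residual > cfg.residual_fraction_tol * max(injected, 1e-300) \
            and it < cfg.max_scattering_iterations:
        it += 1
        residual = scattering_iteration(scene, cfg, props, field_, it)
        ledger.append(dict(iteration=it, **field_.ledger_row()))
        if on_iteration is not None:
            on_iteration(field_, it)
    if residual > cfg.residual_fraction_tol * max(injected, 1e-300):
        warnings.warn(
            f"transport did not converge in {cfg.max_scattering_iterations} "
            f"iterations; residual {residual:.3e} W of {injected:.3e} W "
            "injected", stacklevel=2)
    return field_, ledger
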