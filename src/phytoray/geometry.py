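"""Scenes of planar primitives: construction, import, and ray intersection.

World frame is right-handed with +z up; all lengths in metres.  Every
surface in a scene is a planar primitive -- a triangle or a rectangular
patch -- carrying two-sided optical properties (material references), an
emissivity, and an open-ended ``data`` map of per-primitive annotation
values (plant id, chlorophyll concentration, temperature, ...).  Patches may
be cut out by a boolean texture mask (e.g. the alpha channel of a leaf PNG):
masked-out texels are fully transparent to rays and excluded from the area.

Ray-scene intersection is exact nearest-hit against all primitives.  The
production kernel (:meth:`Scene.intersect`) is a chunked, fully vectorised
numpy implementation whose semantics are pinned by a scalar brute-force
oracle in the test-suite; there is no spatial acceleration structure because
at the scale this package targets the batched kernel is already faster than
a Python-level hierarchy traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .spectra import Spectrum

#: minimum ray-surface distance; avoids self-intersection after scattering
INTERSECT_EPS = 1e-6

#: alpha threshold above which a texel is opaque
ALPHA_THRESHOLD = 0.5


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero-length vector")
    return v / norm


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Intrinsic rotations about x, then y, then z (radians)."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class Material:
    """Named optical properties of a surface.

    Either spectral (rho/tau spectra, integrated per band during transport
    setup) or explicit per-band values via ``band_overrides``
    (label -> (rho, tau)); overrides win.  Longwave behaviour is derived
    from the primitive emissivity, not from the material.
    """

    name: str
    rho_spectrum: Optional[Spectrum] = None
    tau_spectrum: Optional[Spectrum] = None
    band_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class Primitive:
    """A planar scene element (triangle or rectangular patch)."""

    uid: int
    kind: str                      # 'triangle' | 'patch'
    vertices: np.ndarray           # (3,3) or (4,3)
    material_front: str = "default"
    material_back: Optional[str] = None     # None -> same as front
    emissivity: float = 0.95
    texture_mask: Optional[np.ndarray] = None   # bool (nu, nv), patches only
    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.kind == "triangle":
            if self.vertices.shape != (3, 3):
                raise ValueError("triangle needs 3 vertices")
        elif self.kind == "patch":
            if self.vertices.shape != (4, 3):
                raise ValueError("patch needs 4 vertices")
        else:
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if not 0.0 <= self.emissivity <= 1.0:
            raise ValueError("emissivity must lie in [0, 1]")
        if self.area <= 0:
            raise ValueError("degenerate primitive: zero area")

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        return v[1] - v[0], v[3] - v[0] if self.kind == "patch" else v[2] - v[0]

    @property
    def normal(self) -> np.ndarray:
        e1, e2 = self.edges
        return _unit(np.cross(e1, e2))

    @property
    def fill_fraction(self) -> float:
        if self.texture_mask is None:
            return 1.0
        m = self.texture_mask
        return float(m.sum()) / m.size if m.size else 0.0

    @property
    def area(self) -> float:
        e1, e2 = self.edges
        full = np.linalg.norm(np.cross(e1, e2))
        if self.kind == "triangle":
            return 0.5 * full
        return full * self.fill_fraction

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def make_patch(center, size, rotation=(0.0, 0.0, 0.0),
               mask: Optional[np.ndarray] = None, uid: int = 0,
               **kwargs) -> Primitive:
    """Rectangular patch centred at ``center``.

    ``size`` is (width, height) in metres in the patch's local x/y before
    ``rotation`` (Euler xyz, radians) is applied; the unrotated normal is
    +z.  ``mask`` is an optional boolean grid cut-out.
    """
    w, h = (float(size), float(size)) if np.isscalar(size) else map(float, size)
    if w <= 0 or h <= 0:
        raise ValueError("patch size must be positive")
    R = rotation if np.shape(rotation) == (3, 3) else rotation_matrix(*rotation)
    local = np.array([[-w / 2, -h / 2, 0], [w / 2, -h / 2, 0],
                      [w / 2, h / 2, 0], [-w / 2, h / 2, 0]])
    verts = local @ np.asarray(R).T + np.asarray(center, dtype=float)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = mask > ALPHA_THRESHOLD
    return Primitive(uid=uid, kind="patch", vertices=verts,
                     texture_mask=mask, **kwargs)


def mask_from_png(path) -> np.ndarray:
    """Boolean cut-out mask from the alpha channel of a PNG (alpha > 0.5)."""
    from PIL import Image

    img = Image.open(path).convert("RGBA")
    alpha = np.asarray(img)[..., 3] / 255.0
    # image row 0 is top; mask axis 0 follows patch local +x, axis 1 +y
    return (alpha.T[:, ::-1]) > ALPHA_THRESHOLD


def import_mesh(path, material: str = "default", uid_start: int = 0,
                **kwargs) -> list[Primitive]:
    """Import a PLY/OBJ mesh as one triangle primitive per face.

    Degenerate (zero-area) faces are skipped with a count in the log.
    """
    import logging

    import trimesh

    mesh = trimesh.load(path, force="mesh", process=False)
    tris = np.asarray(mesh.triangles, dtype=float)
    if tris.size == 0:
        raise ValueError(f"{path}: mesh has no faces")
    prims, skipped = [], 0
    uid = uid_start
    for tri in tris:
        area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        if area <= 0 or not np.isfinite(area):
            skipped += 1
            continue
        prims.append(Primitive(uid=uid, kind="triangle", vertices=tri,
                               material_front=material, **kwargs))
        uid += 1
    if skipped:
        logging.getLogger(__name__).warning(
            "%s: skipped %d degenerate faces", path, skipped)
    if not prims:
        raise ValueError(f"{path}: all faces degenerate")
    return prims


def build_ground(extent, tiles=(1, 1), mask: Optional[np.ndarray] = None,
                 material: str = "ground", uid_start: int = 0,
                 center=(0.0, 0.0, 0.0), data: Optional[dict] = None
                 ) -> list[Primitive]:
    """Horizontal ground made of a regular grid of textured patches."""
    w, h = (float(extent), float(extent)) if np.isscalar(extent) \
        else map(float, extent)
    nx, ny = tiles
    tw, th = w / nx, h / ny
    cx, cy, cz = center
    prims = []
    uid = uid_start
    for j in range(ny):
        for i in range(nx):
            c = (cx - w / 2 + (i + 0.5) * tw, cy - h / 2 + (j + 0.5) * th, cz)
            d = dict(data or {})
            prims.append(make_patch(c, (tw, th), mask=mask, uid=uid,
                                    material_front=material, data=d))
            uid += 1
    return prims


# ---------------------------------------------------------------------------
# radiation sources

EXTERNAL_SOURCE_KINDS = ("collimated_sun", "sun_sphere", "sphere", "disk",
                         "rectangle")
SKY_SOURCE_KINDS = ("diffuse_sky", "longwave_sky")

#: angular radius of the solar disk seen from Earth (degrees)
SUN_ANGULAR_RADIUS_DEG = 0.266


@dataclass
class RadiationSource:
    """A radiation source.

    Kinds and their flux conventions:

    * ``collimated_sun`` / ``sun_sphere``: ``direction`` points from the
      scene toward the sun; ``band_fluxes`` is the irradiance (W m^-2) on a
      plane normal to the beam.  ``sun_sphere`` samples a disk of angular
      radius 0.266 deg, giving penumbras; collimated is its zero-width
      limit.
    * ``sphere`` / ``disk`` / ``rectangle``: terrestrial sources (lamp, LED
      panel) at ``position``; ``band_fluxes`` holds total emitted power per
      band in watts.  Spheres emit isotropically, planar sources
      cosine-distributed from their ``normal`` side.
    * ``diffuse_sky``: isotropic sky; ``band_fluxes`` is the flux on an
      unobstructed horizontal surface.
    * ``longwave_sky``: as above with the flux fixed to sigma*T_sky^4 in
      every longwave band.

    ``spectral_distribution`` (S_lambda) is required for external kinds: it
    sets the spectral weighting of band properties.
    """

    kind: str
    direction: Optional[np.ndarray] = None
    position: Optional[np.ndarray] = None
    normal: Optional[np.ndarray] = None
    radius: float = 0.0
    extent: tuple[float, float] = (0.0, 0.0)
    band_fluxes: dict[str, float] = field(default_factory=dict)
    sky_temperature: Optional[float] = None
    spectral_distribution: Optional[Spectrum] = None

    def __post_init__(self) -> None:
        if self.kind not in EXTERNAL_SOURCE_KINDS + SKY_SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.kind in ("collimated_sun", "sun_sphere"):
            if self.direction is None:
                raise ValueError(f"{self.kind} requires a direction")
            self.direction = _unit(self.direction)
        if self.kind in ("sphere", "disk", "rectangle"):
            if self.position is None:
                raise ValueError(f"{self.kind} requires a position")
            self.position = np.asarray(self.position, dtype=float)
        if self.kind in ("disk", "rectangle"):
            if self.normal is None:
                raise ValueError(f"{self.kind} requires a normal")
            self.normal = _unit(self.normal)
        if self.kind == "longwave_sky" and self.sky_temperature is None:
            raise ValueError("longwave_sky requires sky_temperature")
        if self.kind in EXTERNAL_SOURCE_KINDS and self.spectral_distribution is None:
            # a flat spectrum is a valid default weighting; keep explicit
            self.spectral_distribution = Spectrum.constant(1.0)
        if any(v < 0 for v in self.band_fluxes.values()):
            raise ValueError("band fluxes must be non-negative")

    @property
    def is_external(self) -> bool:
        return self.kind in EXTERNAL_SOURCE_KINDS


# ---------------------------------------------------------------------------
# scene container + intersection kernel


class Scene:
    """A collection of primitives, materials, and radiation sources."""

    def __init__(self, primitives: Sequence[Primitive] = (),
                 materials: Optional[dict[str, Material]] = None,
                 sources: Sequence[RadiationSource] = ()):
        self.primitives: list[Primitive] = list(primitives)
        self.materials: dict[str, Material] = dict(materials or {})
        self.sources: list[RadiationSource] = list(sources)
        self._compiled = None
        uids = [p.uid for p in self.primitives]
        if len(set(uids)) != len(uids):
            raise ValueError("primitive uids must be unique")

    # -- mutation ------------------------------------------------------

    def add(self, prims) -> None:
        if isinstance(prims, Primitive):
            prims = [prims]
        existing = {p.uid for p in self.primitives}
        for p in prims:
            if p.uid in existing:
                raise ValueError(f"duplicate primitive uid {p.uid}")
            existing.add(p.uid)
        self.primitives.extend(prims)
        self._compiled = None

    def add_material(self, mat: Material) -> None:
        self.materials[mat.name] = mat

    def next_uid(self) -> int:
        return 1 + max((p.uid for p in self.primitives), default=-1)

    # -- queries -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.primitives)

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.primitives:
            raise ValueError("empty scene has no bounding box")
        pts = np.concatenate([p.vertices for p in self.primitives])
        return pts.min(axis=0), pts.max(axis=0)

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        M = len(self.primitives)
        V0 = np.zeros((M, 3))
        E1 = np.zeros((M, 3))
        E2 = np.zeros((M, 3))
        NRM = np.zeros((M, 3))
        is_tri = np.zeros(M, dtype=bool)
        mask_off = np.full(M, -1, dtype=np.int64)
        mask_nu = np.zeros(M, dtype=np.int64)
        mask_nv = np.zeros(M, dtype=np.int64)
        flat_masks = []
        off = 0
        for m, p in enumerate(self.primitives):
            v = p.vertices
            V0[m] = v[0]
            e1, e2 = p.edges
            E1[m], E2[m] = e1, e2
            NRM[m] = p.normal
            is_tri[m] = p.kind == "triangle"
            if p.texture_mask is not None:
                mm = np.asarray(p.texture_mask, dtype=bool)
                mask_off[m] = off
                mask_nu[m], mask_nv[m] = mm.shape
                flat_masks.append(mm.ravel())
                off += mm.size
        flat_mask = (np.concatenate(flat_masks) if flat_masks
                     else np.zeros(0, dtype=bool))
        # gram inverse for (alpha, beta) local coordinates
        e11 = (E1 * E1).sum(1)
        e12 = (E1 * E2).sum(1)
        e22 = (E2 * E2).sum(1)
        det = e11 * e22 - e12 ** 2
        self._compiled = dict(
            V0=V0, E1=E1, E2=E2, NRM=NRM, is_tri=is_tri,
            g_a1=e22 / det, g_a2=-e12 / det, g_b1=-e12 / det, g_b2=e11 / det,
            v0n=(V0 * NRM).sum(1), v0e1=(V0 * E1).sum(1), v0e2=(V0 * E2).sum(1),
            mask_off=mask_off, mask_nu=mask_nu, mask_nv=mask_nv,
            flat_mask=flat_mask,
        )
        return self._compiled

    def intersect(self, origins, directions, eps: float = INTERSECT_EPS,
                  chunk: int = 1024):
        """Nearest-hit intersection for a batch of rays.

        Parameters
        ----------
        origins, directions : (N, 3) arrays; directions must be unit length.

        Returns
        -------
        idx : (N,) int -- index into ``scene.primitives`` (-1 for a miss)
        t : (N,) float -- hit distance (inf for a miss)
        side : (N,) int -- 0 if the front face was hit, 1 for the back
        """
        O = np.atleast_2d(np.asarray(origins, dtype=float))
        D = np.atleast_2d(np.asarray(directions, dtype=float))
        N = O.shape[0]
        idx = np.full(N, -1, dtype=np.int64)
        tt = np.full(N, np.inf)
        side = np.zeros(N, dtype=np.int64)
        if not self.primitives:
            return idx, tt, side
        c = self._compile()
        for lo in range(0, N, chunk):
            hi = min(lo + chunk, N)
            o, d = O[lo:hi], D[lo:hi]
            dn = d @ c["NRM"].T                               # (n, M)
            on = o @ c["NRM"].T
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (c["v0n"][None, :] - on) / dn
            valid = (np.abs(dn) > 1e-12) & (t > eps) & np.isfinite(t)
            de1 = d @ c["E1"].T
            oe1 = o @ c["E1"].T
            de2 = d @ c["E2"].T
            oe2 = o @ c["E2"].T
            pe1 = oe1 + t * de1 - c["v0e1"][None, :]
            pe2 = oe2 + t * de2 - c["v0e2"][None, :]
            alpha = c["g_a1"] * pe1 + c["g_a2"] * pe2
            beta = c["g_b1"] * pe1 + c["g_b2"] * pe2
            tol = 1e-9
            inside_tri = (alpha >= -tol) & (beta >= -tol) & (alpha + beta <= 1 + tol)
            inside_pat = (alpha >= -tol) & (alpha <= 1 + tol) \
                & (beta >= -tol) & (beta <= 1 + tol)
            inside = np.where(c["is_tri"][None, :], inside_tri, inside_pat)
            valid &= inside
            # texture-mask transparency
            has_mask = c["mask_off"] >= 0
            if c["flat_mask"].size:
                cand = valid & has_mask[None, :]
                if cand.any():
                    rr, mm = np.nonzero(cand)
                    iu = np.clip((alpha[rr, mm] * c["mask_nu"][mm]).astype(np.int64),
                                 0, c["mask_nu"][mm] - 1)
                    iv = np.clip((beta[rr, mm] * c["mask_nv"][mm]).astype(np.int64),
                                 0, c["mask_nv"][mm] - 1)
                    opaque = c["flat_mask"][c["mask_off"][mm] + iu * c["mask_nv"][mm] + iv]
                    valid[rr[~opaque], mm[~opaque]] = False
            t = np.where(valid, t, np.inf)
            best = np.argmin(t, axis=1)
            rows = np.arange(t.shape[0])
            tbest = t[rows, best]
            hit = np.isfinite(tbest)
            idx[lo:hi][hit] = best[hit]
            tt[lo:hi][hit] = tbest[hit]
            side[lo:hi][hit] = (dn[rows, best][hit] > 0).astype(np.int64)
        return idx, tt, side

    def intersect_one(self, origin, direction, eps: float = INTERSECT_EPS):
        """Single-ray convenience wrapper around :meth:`intersect`."""
        idx, t, side = self.intersect(np.asarray(origin)[None, :],
                                      np.asarray(direction)[None, :], eps=eps)
        return int(idx[0]), float(t[0]), int(side[0])

    # -- surface sampling (used by the transport module) ---------------

    def sample_points(self, prim_index: int, n: int,
                      rng: np.random.Generator) -> np.ndarray:
        """Uniform random points on a primitive's (opaque) surface."""
        p = self.primitives[prim_index]
        e1, e2 = p.edges
        if p.kind == "triangle":
            u = rng.random(n)
            v = rng.random(n)
            flip = u + v > 1
            u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
        else:
            if p.texture_mask is not None:
                m = p.texture_mask
                opaque = np.flatnonzero(m.ravel())
                tex = opaque[rng.integers(0, opaque.size, n)]
                iu, iv = np.divmod(tex, m.shape[1])
                u = (iu + rng.random(n)) / m.shape[0]
                v = (iv + rng.random(n)) / m.shape[1]
            else:
                u = rng.random(n)
                v = rng.random(n)
        return p.vertices[0] + u[:, None] * e1 + v[:, None] * e2
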