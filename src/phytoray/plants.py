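"""Procedural plant and canopy generation.

Deliberately simplified parametric plants (stem / petiole / leaf / fruit
placement with seeded random variation): their contract is statistical --
element counts and sizes inside the configured ranges, full determinism
under a fixed seed, and complete annotation data (``plant_id``,
``leaf_id``, ``organ`` on every primitive) -- not geometric fidelity to any
particular crop architecture model.

Three presets are provided.  The strawberry-like preset follows the study
conditions used for synthetic strawberry imagery: plant height 0.2-0.4 m,
berry radius 0.04-0.08 m, leaf length 0.05-0.1 m, 15 stems per plant and
1-3 berries per stem, all scaled by 0.8.  The bean-like and sorghum-like
presets use realistic desk-scale ranges chosen once and documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Primitive, make_patch, rotation_matrix


def ellipse_mask(n: int = 24, aspect: float = 1.0) -> np.ndarray:
    """Boolean elliptical cut-out used as a generic leaf silhouette."""
    u = (np.arange(n) + 0.5) / n * 2 - 1
    xx, yy = np.meshgrid(u, u, indexing="ij")
    return (xx ** 2 + (yy / aspect) ** 2) <= 1.0


@dataclass(frozen=True)
class ProceduralPlantParams:
    """Ranges controlling a procedural plant. All lengths in metres."""

    species: str = "bean-like"
    plant_height_range: tuple[float, float] = (0.15, 0.25)
    leaf_length_range: tuple[float, float] = (0.05, 0.09)
    leaves_per_petiole: int = 3
    stems_per_plant: tuple[int, int] = (1, 3)
    fruit_radius_range: tuple[float, float] = (0.0, 0.0)
    fruit_count_per_stem: tuple[int, int] = (0, 0)
    rotation_jitter: tuple[float, float, float] = (0.3, 0.3, np.pi)
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("plant_height_range", "leaf_length_range",
                     "fruit_radius_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be ordered and non-negative")
        for name in ("stems_per_plant", "fruit_count_per_stem"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be ordered and non-negative")


def species_preset(species: str, seed: int = 0, **overrides) -> ProceduralPlantParams:
    """Named parameter presets; ``overrides`` replace individual fields."""
    presets = {
        "bean-like": dict(
            species="bean-like",
            plant_height_range=(0.15, 0.25), leaf_length_range=(0.05, 0.09),
            leaves_per_petiole=3, stems_per_plant=(1, 3),
            rotation_jitter=(0.3, 0.3, np.pi)),
        "strawberry-like": dict(
            species="strawberry-like",
            plant_height_range=(0.2, 0.4), leaf_length_range=(0.05, 0.1),
            leaves_per_petiole=3, stems_per_plant=(15, 15),
            fruit_radius_range=(0.04, 0.08), fruit_count_per_stem=(1, 3),
            rotation_jitter=(0.3, 0.3, np.pi), scale=0.8),
        "sorghum-like": dict(
            species="sorghum-like",
            plant_height_range=(0.8, 1.4), leaf_length_range=(0.3, 0.6),
            leaves_per_petiole=1, stems_per_plant=(1, 1),
            rotation_jitter=(0.2, 0.2, np.pi)),
    }
    if species not in presets:
        raise ValueError(f"unknown species preset {species!r}")
    return replace(ProceduralPlantParams(**presets[species]), seed=seed,
                   **overrides)


def _icosahedron(center: np.ndarray, radius: float) -> np.ndarray:
    """Vertices of the 20 faces of an icosahedron (used for fruit)."""
    phi = (1 + np.sqrt(5)) / 2
    v = np.array([[-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
                  [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
                  [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1]],
                 dtype=float)
    v /= np.linalg.norm(v[0])
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]])
    return v[faces] * radius + center


def build_plant(params: ProceduralPlantParams, origin=(0.0, 0.0, 0.0),
                plant_id: int = 0, uid_start: int = 0,
                leaf_mask: np.ndarray | None = None) -> list[Primitive]:
    """Generate one plant; deterministic for a fixed ``params.seed``.

    Every primitive carries ``plant_id`` and ``organ``; leaves additionally
    carry ``leaf_id``, fruits ``fruit_id``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, plant_id]))
    origin = np.asarray(origin, dtype=float)
    s = params.scale
    if leaf_mask is None:
        leaf_mask = ellipse_mask(24, aspect=0.6)
    prims: list[Primitive] = []
    uid = uid_start
    leaf_id = 0
    fruit_id = 0
    jx, jy, jz = params.rotation_jitter

    n_stems = int(rng.integers(params.stems_per_plant[0],
                               params.stems_per_plant[1] + 1))
    plant_yaw = rng.uniform(-jz, jz)
    for istem in range(n_stems):
        height = rng.uniform(*params.plant_height_range) * s
        azim = plant_yaw + 2 * np.pi * istem / max(n_stems, 1) \
            + rng.uniform(-0.3, 0.3)
        tilt = rng.uniform(0.05, 0.35)
        top = origin + height * np.array([np.sin(tilt) * np.cos(azim),
                                          np.sin(tilt) * np.sin(azim),
                                          np.cos(tilt)])
        # stem: two crossed thin quads along the axis
        axis = top - origin
        mid = origin + axis / 2
        stem_rot = rotation_matrix(tilt * np.sin(azim), -tilt * np.cos(azim), 0)
        for roll in (0.0, np.pi / 2):
            R = stem_rot @ rotation_matrix(0, 0, roll) \
                @ rotation_matrix(np.pi / 2, 0, 0)
            prims.append(make_patch(
                mid, (0.004 * s, height), rotation=R, uid=uid,
                material_front="stem",
                data={"plant_id": plant_id, "organ": "stem"}))
            uid += 1
        # leaves on a petiole whorl at the stem top
        for ileaf in range(params.leaves_per_petiole):
            length = rng.uniform(*params.leaf_length_range) * s
            width = length * 0.6
            la = azim + 2 * np.pi * ileaf / max(params.leaves_per_petiole, 1) \
                + rng.uniform(-jz / 6, jz / 6)
            droop = 0.9 + rng.uniform(-jx, jx)
            R = rotation_matrix(0, 0, la) @ rotation_matrix(0, droop, 0) \
                @ rotation_matrix(rng.uniform(-jy, jy), 0, 0)
            cen = top + R @ np.array([length / 2 + 0.01 * s, 0, 0])
            prims.append(make_patch(
                cen, (length, width),
                rotation=R @ rotation_matrix(0, np.pi / 2, 0),
                mask=leaf_mask, uid=uid, material_front="leaf",
                data={"plant_id": plant_id, "leaf_id": leaf_id,
                      "organ": "leaf", "leaf_length_m": length}))
            uid += 1
            leaf_id += 1
        # fruit hanging low on the stem
        n_fruit = int(rng.integers(params.fruit_count_per_stem[0],
                                   params.fruit_count_per_stem[1] + 1)) \
            if params.fruit_count_per_stem[1] > 0 else 0
        for _ in range(n_fruit):
            radius = rng.uniform(*params.fruit_radius_range) * s
            h = rng.uniform(0.2, 0.5) * height
            pos = origin + (top - origin) * h / height \
                + np.array([rng.uniform(-0.02, 0.02) * s,
                            rng.uniform(-0.02, 0.02) * s, 0])
            pos[2] = max(pos[2], radius * 1.05)
            for tri in _icosahedron(pos, radius):
                prims.append(Primitive(
                    uid=uid, kind="triangle", vertices=tri,
                    material_front="fruit",
                    data={"plant_id": plant_id, "fruit_id": fruit_id,
                          "organ": "fruit"}))
                uid += 1
            fruit_id += 1
    return prims


def build_canopy(params: ProceduralPlantParams, rows: int = 2, cols: int = 2,
                 spacing: float = 0.4, uid_start: int = 0) -> list[Primitive]:
    """A regular grid of plants with per-plant seeds derived from params.seed."""
    prims: list[Primitive] = []
    uid = uid_start
    pid = 0
    x0 = -(cols - 1) * spacing / 2
    y0 = -(rows - 1) * spacing / 2
    for r in range(rows):
        for c in range(cols):
            plant = build_plant(params, origin=(x0 + c * spacing,
                                                y0 + r * spacing, 0.0),
                                plant_id=pid, uid_start=uid)
            prims.extend(plant)
            uid = 1 + max(p.uid for p in plant)
            pid += 1
    return prims
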