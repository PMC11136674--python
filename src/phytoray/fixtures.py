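"""Canonical test scenes with analytically known expectations.

These fixtures make the package testable without any external data: each
returns a fully specified :class:`~phytoray.geometry.Scene` plus a record
of closed-form expected values.

* ``single_plate`` -- one horizontal 1 m^2 plate (rho=0.3, tau=0.2) under a
  collimated zenith source of 1000 W m^-2: absorbed flux is exactly
  ``(1 - rho - tau) * S * cos(theta)`` and a downward-looking camera reads
  ``rho_o * S * cos(theta)``.
* ``occlusion_pair`` -- two stacked plates; the nearer one must win every
  annotation ray it covers.
* ``mini_canopy`` -- textured ground plus a small procedural bean canopy
  under direct sun and diffuse sky, two shortwave bands; used for
  energy-ledger checks (a few hundred primitives).
* ``color_board`` -- an 18-patch reflectance board with seeded smooth
  random spectra and a matching scene, for calibration studies.
"""

from __future__ import annotations

import numpy as np

from .calibration import ColorTarget
from .geometry import Material, RadiationSource, Scene, make_patch
from .plants import build_canopy, species_preset
from .spectra import Spectrum, WaveBand

FIXTURE_NAMES = ("single_plate", "occlusion_pair", "mini_canopy",
                 "color_board")


def _smooth_reflectance(rng: np.random.Generator,
                        grid: np.ndarray) -> Spectrum:
    v = np.zeros_like(grid)
    for _ in range(4):
        mu = rng.uniform(grid[0], grid[-1])
        sig = rng.uniform(30, 120)
        v += rng.uniform(0.0, 0.9) * np.exp(-0.5 * ((grid - mu) / sig) ** 2)
    return Spectrum(grid, np.clip(v, 0.02, 0.95))


def generate_fixture(name: str, seed: int = 0) -> tuple[Scene, dict]:
    """Build a canonical scene; returns (scene, expected-value record)."""
    if name == "single_plate":
        band = WaveBand("sw", 400, 700)
        rho, tau, S = 0.3, 0.2, 1000.0
        mat = Material("plate", band_overrides={"sw": (rho, tau)})
        plate = make_patch((0.0, 0.0, 0.0), (1.0, 1.0), uid=0,
                           material_front="plate",
                           data={"plant_id": 1, "temperature": 300.0})
        sun = RadiationSource("collimated_sun", direction=[0, 0, 1],
                              band_fluxes={"sw": S})
        scene = Scene([plate], {"plate": mat}, [sun])
        expected = {
            "band": band, "rho": rho, "tau": tau, "source_flux": S,
            "absorbed_flux": (1 - rho - tau) * S,
            "camera_pixel": rho * S,
            "absorbed_flux_60deg": (1 - rho - tau) * S * 0.5,
        }
        return scene, expected

    if name == "occlusion_pair":
        band = WaveBand("sw", 400, 700)
        mat = Material("grey", band_overrides={"sw": (0.5, 0.0)})
        back = make_patch((0.0, 0.0, 0.0), (2.0, 2.0), uid=10,
                          material_front="grey",
                          data={"plant_id": 1, "temperature": 290.0})
        front = make_patch((0.0, 0.0, 1.0), (0.6, 0.6), uid=20,
                           material_front="grey",
                           data={"plant_id": 2, "temperature": 305.0})
        sun = RadiationSource("collimated_sun", direction=[0, 0, 1],
                              band_fluxes={"sw": 800.0})
        scene = Scene([back, front], {"grey": mat}, [sun])
        return scene, {"band": band, "front_uid": 20, "back_uid": 10,
                       "front_z": 1.0, "back_z": 0.0}

    if name == "mini_canopy":
        red = WaveBand("red", 600, 700)
        nir = WaveBand("nir", 750, 900)
        mats = {
            "leaf": Material("leaf", band_overrides={"red": (0.08, 0.06),
                                                     "nir": (0.45, 0.45)}),
            "stem": Material("stem", band_overrides={"red": (0.15, 0.0),
                                                     "nir": (0.35, 0.0)}),
            "fruit": Material("fruit", band_overrides={"red": (0.30, 0.0),
                                                       "nir": (0.40, 0.0)}),
            "ground": Material("ground", band_overrides={"red": (0.20, 0.0),
                                                         "nir": (0.25, 0.0)}),
        }
        from .geometry import build_ground

        prims = build_ground((2.0, 2.0), (2, 2), material="ground",
                             data={"plant_id": 0, "temperature": 300.0})
        params = species_preset("bean-like", seed=seed)
        canopy = build_canopy(params, rows=2, cols=2, spacing=0.5,
                              uid_start=100)
        for p in canopy:
            p.data.setdefault("temperature", 298.0)
            p.data["plant_id"] = p.data.get("plant_id", 0) + 1
        prims.extend(canopy)
        sun = RadiationSource(
            "collimated_sun",
            direction=[np.sin(np.pi / 6), 0, np.cos(np.pi / 6)],
            band_fluxes={"red": 400.0, "nir": 350.0})
        sky = RadiationSource("diffuse_sky",
                              band_fluxes={"red": 60.0, "nir": 50.0})
        scene = Scene(prims, mats, [sun, sky])
        if len(scene) > 500:
            raise AssertionError("mini_canopy exceeded its primitive budget")
        return scene, {"bands": [red, nir], "n_primitives": len(scene)}

    if name == "color_board":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
        grid = np.arange(400.0, 701.0)
        names = [f"patch{i:02d}" for i in range(18)]
        target = ColorTarget({n: _smooth_reflectance(rng, grid)
                              for n in names})
        mats, prims = {}, []
        for i, n in enumerate(names):
            mats[n] = Material(n, rho_spectrum=target.patches[n])
            r, c = divmod(i, 6)
            prims.append(make_patch((0.11 * (c - 2.5), 0.11 * (1 - r), 0.0),
                                    (0.1, 0.1), uid=i, material_front=n,
                                    data={"patch_index": i}))
        sun = RadiationSource("collimated_sun", direction=[0, 0, 1],
                              band_fluxes={"r": 300.0, "g": 300.0, "b": 300.0},
                              spectral_distribution=Spectrum(
                                  grid, 1.0 + 0.3 * np.sin(grid / 80.0)))
        scene = Scene(prims, mats, [sun])
        bands = [WaveBand("r", 580, 680), WaveBand("g", 480, 580),
                 WaveBand("b", 400, 490)]
        return scene, {"target": target, "bands": bands,
                       "illuminant": sun.spectral_distribution}

    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
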