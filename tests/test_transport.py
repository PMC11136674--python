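"""Radiation transport: closed-form flat-plate radiometry, view factors,
energy bookkeeping, and Monte-Carlo behaviour."""

import numpy as np
import pytest

from phytoray.geometry import (Material, RadiationSource, Scene, build_ground,
                               make_patch)
from phytoray.spectra import SIGMA_SB, WaveBand
from phytoray.transport import (RadiationField, TransportConfig,
                                compute_band_properties, direct_pass,
                                diffuse_pass, emission_pass, run_transport,
                                scattering_iteration)

SW = WaveBand("sw", 400, 700)
LW = WaveBand("lw", 3000, 14000, longwave=True)


def plate_scene(rho=0.3, tau=0.2, direction=(0, 0, 1), flux=1000.0,
                size=(1.0, 1.0), extra=(), materials=None):
    mat = Material("plate", band_overrides={"sw": (rho, tau)})
    mats = {"plate": mat, **(materials or {})}
    plate = make_patch((0, 0, 0), size, uid=0, material_front="plate")
    sun = RadiationSource("collimated_sun", direction=direction,
                          band_fluxes={"sw": flux})
    return Scene([plate, *extra], mats, [sun])


class TestDirectPass:
    def test_flat_plate_zenith_closed_form(self):
        field, _ = run_transport(plate_scene(), [SW], TransportConfig(seed=1))
        assert field.absorbed.sum() == pytest.approx(500.0, rel=1e-12)

    def test_cosine_law_at_60_degrees(self):
        d = (np.sin(np.pi / 3), 0.0, np.cos(np.pi / 3))
        field, _ = run_transport(plate_scene(direction=d), [SW],
                                 TransportConfig(seed=1))
        assert field.absorbed.sum() == pytest.approx(250.0, rel=1e-12)

    def test_fully_shadowed_plate_gets_nothing(self):
        shade = make_patch((0, 0, 1), (5, 5), uid=9, material_front="opaque")
        sc = plate_scene(extra=[shade], materials={
            "opaque": Material("opaque", band_overrides={"sw": (0.0, 0.0)})})
        field, _ = run_transport(sc, [SW], TransportConfig(seed=1))
        assert field.incident[0].sum() == 0.0

    def test_sun_sphere_approaches_collimated_limit(self):
        sc = plate_scene()
        sc.sources[0] = RadiationSource("sun_sphere", direction=[0, 0, 1],
                                        band_fluxes={"sw": 1000.0})
        field, _ = run_transport(sc, [SW], TransportConfig(seed=1))
        # 0.266 deg half-angle: cos factor within 1e-5 of 1
        assert field.absorbed.sum() == pytest.approx(500.0, rel=1e-4)

    def test_sphere_source_inverse_square_law(self):
        mat = Material("plate", band_overrides={"sw": (0.0, 0.0)})
        plate = make_patch((0, 0, 0), (0.1, 0.1), uid=0,
                           material_front="plate")
        lamp = RadiationSource("sphere", position=[0, 0, 4.0], radius=0.02,
                               band_fluxes={"sw": 1000.0})   # 1000 W total
        sc = Scene([plate], {"plate": mat}, [lamp])
        cfg = TransportConfig(seed=2, rays_per_primitive_direct=512)
        field, _ = run_transport(sc, [SW], cfg)
        expect = 1000.0 / (4 * np.pi * 4.0 ** 2)       # cos(theta) = 1
        assert field.incident[0, 0, 0] == pytest.approx(expect, rel=0.02)

    def test_results_invariant_under_primitive_reordering(self):
        a = make_patch((0, 0, 0.0), (1, 1), uid=3, material_front="plate")
        b = make_patch((0.2, 0, 0.5), (1, 1), uid=7, material_front="plate")
        mat = {"plate": Material("plate", band_overrides={"sw": (0.4, 0.1)})}
        sun = RadiationSource("collimated_sun", direction=[0.2, 0.1, 0.95],
                              band_fluxes={"sw": 900.0})
        cfg = TransportConfig(seed=5)
        f1, _ = run_transport(Scene([a, b], mat, [sun]), [SW], cfg)
        f2, _ = run_transport(Scene([b, a], mat, [sun]), [SW], cfg)
        np.testing.assert_array_equal(f1.absorbed[0], f2.absorbed[1])
        np.testing.assert_array_equal(f1.absorbed[1], f2.absorbed[0])


class TestDiffusePass:
    def _sky_scene(self, extra=(), rho=0.3):
        mat = Material("plate", band_overrides={"sw": (rho, 0.0)})
        mats = {"plate": mat,
                "opaque": Material("opaque", band_overrides={"sw": (0.0, 0.0)})}
        plate = make_patch((0, 0, 0), (1, 1), uid=0, material_front="plate")
        sky = RadiationSource("diffuse_sky", band_fluxes={"sw": 200.0})
        return Scene([plate, *extra], mats, [sky])

    def test_unobstructed_plate_sees_full_sky(self):
        field, _ = run_transport(self._sky_scene(), [SW],
                                 TransportConfig(seed=1))
        # every upward cosine ray escapes: exactly D on the top side
        assert field.incident[0, 0, 0] == pytest.approx(200.0)

    def test_plate_inside_closed_box_sees_nothing(self):
        box = []
        uid = 10
        for c, rot in [((0, 0, 2), (np.pi, 0, 0)), ((0, 0, -2), (0, 0, 0)),
                       ((2, 0, 0), (0, -np.pi / 2, 0)),
                       ((-2, 0, 0), (0, np.pi / 2, 0)),
                       ((0, 2, 0), (np.pi / 2, 0, 0)),
                       ((0, -2, 0), (-np.pi / 2, 0, 0))]:
            box.append(make_patch(c, (4.0, 4.0), rotation=rot, uid=uid,
                                  material_front="opaque"))
            uid += 1
        field, _ = run_transport(self._sky_scene(extra=box), [SW],
                                 TransportConfig(seed=1))
        assert field.incident[0].sum() == 0.0

    def test_half_sky_overhang_view_factor(self):
        # semi-infinite horizontal overhang with its edge over the plate
        # centre blocks exactly half the cosine-weighted sky
        overhang = make_patch((500.0, 0, 1.0), (1000.0, 1000.0), uid=5,
                              material_front="opaque")
        field, _ = run_transport(
            self._sky_scene(extra=[overhang]), [SW],
            TransportConfig(seed=3, rays_per_primitive_diffuse=2000))
        est = field.incident[0, 0, 0]
        se = 200.0 * 0.5 / np.sqrt(2000)          # binomial standard error
        assert abs(est - 100.0) < 3 * se + 1e-9


class TestEmission:
    def test_cold_scene_has_no_longwave_field(self):
        sc = plate_scene()
        sc.primitives[0].data["temperature"] = 0.0
        field, _ = run_transport(sc, [LW], TransportConfig(seed=1))
        assert field.injected.sum() == 0.0

    def test_isolated_plate_emits_stefan_boltzmann_per_side(self):
        sc = plate_scene()
        sc.primitives[0].data["temperature"] = 300.0
        sc.primitives[0].emissivity = 1.0
        cfg = TransportConfig(seed=1)
        props = compute_band_properties(sc, [LW])
        field = RadiationField(1, [LW], np.array([p.area for p in sc.primitives]))
        emission_pass(sc, cfg, props, field)
        expect = SIGMA_SB * 300.0 ** 4
        np.testing.assert_allclose(field.tbs_band[0, 0], [expect, expect])

    def test_missing_temperature_without_default_errors(self):
        sc = plate_scene()
        with pytest.raises(ValueError):
            run_transport(sc, [LW], TransportConfig(seed=1))

    def test_facing_black_plates_exchange_sigma_t4_difference(self):
        mat = {"black": Material("black")}
        hot = make_patch((0, 0, 0), (10, 10), uid=0, material_front="black",
                         emissivity=1.0, data={"temperature": 400.0})
        cold = make_patch((0, 0, 0.01), (10, 10), rotation=(np.pi, 0, 0),
                          uid=1, material_front="black", emissivity=1.0,
                          data={"temperature": 300.0})
        sc = Scene([hot, cold], mat, [])
        cfg = TransportConfig(seed=4, rays_per_primitive_diffuse=256)
        field, _ = run_transport(sc, [LW], cfg)
        # facing sides: hot front (up), cold front (down); absorbed is flux
        got_cold = field.absorbed[1, 0, 0]
        got_hot = field.absorbed[0, 0, 0]
        net = got_cold - got_hot
        expect = SIGMA_SB * (400.0 ** 4 - 300.0 ** 4)
        assert net == pytest.approx(expect, rel=0.02)   # gap->0 view factor


class TestScattering:
    def test_black_scene_converges_immediately(self):
        sc = plate_scene(rho=0.0, tau=0.0)
        field, ledger = run_transport(sc, [SW], TransportConfig(seed=1))
        assert field.residual_energy().sum() == 0.0
        assert ledger[-1]["iteration"] <= 1

    def test_two_plate_multiple_reflection_series(self):
        mat = {"half": Material("half", band_overrides={"sw": (0.5, 0.0)})}
        a = make_patch((0, 0, 0), (20, 20), uid=0, material_front="half")
        b = make_patch((0, 0, 0.02), (20, 20), rotation=(np.pi, 0, 0), uid=1,
                       material_front="half")
        sc = Scene([a, b], mat, [])
        cfg = TransportConfig(seed=2, rays_per_primitive_diffuse=64,
                              max_scattering_iterations=60,
                              residual_fraction_tol=0.005)
        props = compute_band_properties(sc, [SW])
        field = RadiationField(2, [SW], np.array([400.0, 400.0]))
        field.tbs_band[0, 0, 0] = 1.0 / 400.0     # inject 1 W upward from a
        field.injected[0] = 1.0
        it, residual = 0, np.inf
        while residual > 1e-6 and it < 60:
            it += 1
            residual = scattering_iteration(sc, cfg, props, field, it)
        # geometric series with view factor ~ 1: b absorbs 2/3, a absorbs 1/3
        total = field.absorbed_energy()[0]
        assert total == pytest.approx(1.0, rel=0.02)
        assert field.absorbed[1, 0, 0] * 400 == pytest.approx(2 / 3, rel=0.05)
        assert field.absorbed[0, 0, 0] * 400 == pytest.approx(1 / 3, rel=0.05)

    def test_residual_obeys_contraction_bound(self):
        mat = {"m": Material("m", band_overrides={"sw": (0.45, 0.25)})}
        prims = build_ground((2, 2), (2, 2), material="m")
        lid = make_patch((0, 0, 0.3), (2, 2), rotation=(np.pi, 0, 0), uid=99,
                         material_front="m")
        sun = RadiationSource("collimated_sun", direction=[0.1, 0, 0.99],
                              band_fluxes={"sw": 500.0})
        sc = Scene(prims + [lid], mat, [sun])
        cfg = TransportConfig(seed=6, max_scattering_iterations=0)
        props = compute_band_properties(sc, [SW])
        with pytest.warns(UserWarning):     # 0 iterations: expected residual
            field, _ = run_transport(sc, [SW], cfg, props=props)
        r0 = field.residual_energy().sum()
        bound = 0.45 + 0.25
        residual = r0
        for it in range(1, 6):
            residual = scattering_iteration(sc, cfg, props, field, it)
            assert residual <= bound ** it * r0 * (1 + 1e-9)

    def test_ledger_closes_exactly_each_iteration(self):
        from phytoray.fixtures import generate_fixture

        sc, exp = generate_fixture("mini_canopy", seed=2)
        cfg = TransportConfig(seed=2, rays_per_primitive_direct=8,
                              rays_per_primitive_diffuse=4)
        field, ledger = run_transport(sc, exp["bands"], cfg)
        for row in ledger:
            closure = row["injected_w"] - row["absorbed_w"] \
                - row["escaped_w"] - row["residual_w"]
            assert abs(closure) < 1e-9 * max(row["injected_w"], 1.0)

    def test_same_seed_bit_identical_field(self):
        from phytoray.fixtures import generate_fixture

        sc1, exp = generate_fixture("mini_canopy", seed=3)
        sc2, _ = generate_fixture("mini_canopy", seed=3)
        cfg = TransportConfig(seed=9, rays_per_primitive_direct=4,
                              rays_per_primitive_diffuse=2)
        f1, _ = run_transport(sc1, exp["bands"], cfg)
        f2, _ = run_transport(sc2, exp["bands"], cfg)
        np.testing.assert_array_equal(f1.absorbed, f2.absorbed)
        np.testing.assert_array_equal(f1.tbs_camera, f2.tbs_camera)


class TestMonteCarloConvergence:
    def test_doubling_rays_shrinks_error_like_sqrt2(self):
        # partially occluded plate: visibility estimate carries MC noise
        mat = {"m": Material("m", band_overrides={"sw": (0.0, 0.0)})}
        holes = np.random.default_rng(0).random((16, 16)) > 0.5
        shade = make_patch((0, 0, 1), (1.4, 1.4), mask=holes, uid=1,
                           material_front="m")
        plate = make_patch((0, 0, 0), (1, 1), uid=0, material_front="m")
        sun = RadiationSource("collimated_sun", direction=[0, 0, 1],
                              band_fluxes={"sw": 1000.0})

        def spread(nrays):
            vals = []
            for seed in range(24):
                sc = Scene([plate, shade], mat, [sun])
                cfg = TransportConfig(seed=seed,
                                      rays_per_primitive_direct=nrays)
                f, _ = run_transport(sc, [SW], cfg)
                vals.append(f.incident[0, 0, 0])
            return np.std(vals)

        s1, s2 = spread(32), spread(128)
        # quadrupling rays should halve the spread (allow slack: 24 reps)
        assert 1.3 < s1 / s2 < 3.2


class TestConfigValidation:
    def test_bad_transport_config(self):
        with pytest.raises(ValueError):
            TransportConfig(rays_per_primitive_direct=0)
        with pytest.raises(ValueError):
            TransportConfig(residual_fraction_tol=0.0)

    def test_nonconvergence_warns(self):
        # low-emissivity facing plates: longwave energy bounces in the gap
        # far longer than the allowed two iterations
        mat = {"foil": Material("foil")}
        a = make_patch((0, 0, 0), (50, 50), uid=0, material_front="foil",
                       emissivity=0.05, data={"temperature": 350.0})
        b = make_patch((0, 0, 0.01), (50, 50), rotation=(np.pi, 0, 0), uid=1,
                       material_front="foil", emissivity=0.05,
                       data={"temperature": 300.0})
        sc = Scene([a, b], mat, [])
        cfg = TransportConfig(seed=1, max_scattering_iterations=2,
                              rays_per_primitive_diffuse=4)
        with pytest.warns(UserWarning, match="did not converge"):
            run_transport(sc, [LW], cfg)
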