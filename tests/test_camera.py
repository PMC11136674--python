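"""Thin-lens camera geometry, radiometry, annotation maps, distortion."""

import numpy as np
import pytest

from phytoray.camera import (CameraIntrinsics, CameraPose,
                             DistortionCoefficients, annotate,
                             apply_distortion, depth_image,
                             distortion_shift, image_plane_distance, render,
                             sample_pixel_rays, thermal_image)
from phytoray.fixtures import generate_fixture
from phytoray.geometry import Material, RadiationSource, Scene, make_patch
from phytoray.spectra import SIGMA_SB, WaveBand
from phytoray.transport import TransportConfig


def down_camera(res=33, z=2.0, hfov_deg=40.0, lens=0.0, spp=4, focal=None):
    intr = CameraIntrinsics(hfov=np.deg2rad(hfov_deg), resolution=(res, res),
                            lens_diameter=lens,
                            focal_plane_distance=focal or z,
                            samples_per_pixel=spp)
    pose = CameraPose(position=[0, 0, z], view_direction=[0, 0, -1],
                      up_hint=[0, 1, 0])
    return intr, pose


class TestGeometryOps:
    def test_image_plane_distance_closed_form(self):
        intr = CameraIntrinsics(hfov=np.pi / 2, resolution=(8, 8),
                                sensor_width=0.036)
        assert image_plane_distance(intr) == pytest.approx(0.018)

    def test_image_plane_distance_round_trip(self):
        intr = CameraIntrinsics(hfov=0.61, resolution=(8, 8),
                                sensor_width=0.024)
        d = image_plane_distance(intr)
        assert 2 * d * np.tan(intr.hfov / 2) == pytest.approx(0.024)

    def test_telephoto_limit(self):
        d1 = image_plane_distance(CameraIntrinsics(hfov=0.1, resolution=(4, 4)))
        d2 = image_plane_distance(CameraIntrinsics(hfov=0.01, resolution=(4, 4)))
        assert d2 > d1 * 9

    def test_invalid_hfov_rejected(self):
        with pytest.raises(ValueError):
            CameraIntrinsics(hfov=np.pi, resolution=(4, 4))

    def test_parallel_up_hint_rejected(self):
        with pytest.raises(ValueError):
            CameraPose([0, 0, 0], [0, 0, 1], up_hint=[0, 0, 1])


class TestPixelRays:
    def test_pinhole_origins_at_lens_center(self):
        intr, pose = down_camera(res=9, lens=0.0)
        O, D = sample_pixel_rays(intr, pose, (4, 4), 8, seed=1)
        assert np.allclose(O, pose.position)

    def test_center_pixel_pinhole_points_along_view(self):
        intr, pose = down_camera(res=9)
        # exact pixel centre of the middle pixel: use the centre-ray path
        from phytoray.camera import _center_rays

        O, D = _center_rays(intr, pose)
        mid = D[(9 * 9) // 2]
        np.testing.assert_allclose(mid, [0, 0, -1], atol=1e-12)

    def test_focal_point_collinear_with_pixel_and_lens_center(self):
        # the focal-plane target must lie on the line through the sampled
        # pixel point and the lens centre: reconstruct and check residual
        intr, pose = down_camera(res=9, lens=0.02, z=3.0, focal=1.7)
        O, D = sample_pixel_rays(intr, pose, (2, 6), 16, seed=3)
        d = image_plane_distance(intr)
        fd = intr.focal_plane_distance
        # recover focal points from ray parametrisation: they sit at the
        # plane z = z_cam - fd
        tt = (pose.position[2] - fd - O[:, 2]) / D[:, 2]
        F = O + tt[:, None] * D
        # the matching image-plane points: scale focal offsets back by d/fd
        f, r, u = pose.basis()
        rel = F - (pose.position + fd * f)
        pix = pose.position - d * f - rel * (d / fd)
        # pix, lens centre, F must be collinear
        v1 = F - pose.position
        v2 = pose.position - pix
        cross = np.cross(v1, v2)
        residual = np.linalg.norm(cross, axis=1) / np.linalg.norm(v1, axis=1)
        assert residual.max() < 1e-12

    def test_pixel_outside_resolution_rejected(self):
        intr, pose = down_camera(res=9)
        with pytest.raises(ValueError):
            sample_pixel_rays(intr, pose, (9, 0), 4)

    def test_deterministic_under_seed(self):
        intr, pose = down_camera(res=9, lens=0.01)
        a = sample_pixel_rays(intr, pose, (3, 3), 16, seed=5)
        b = sample_pixel_rays(intr, pose, (3, 3), 16, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestRadiometry:
    def test_flat_plate_pixel_equals_rho_o_times_flux(self):
        scene, exp = generate_fixture("single_plate")
        intr, pose = down_camera(res=17, z=1.0, hfov_deg=30, spp=8)
        prod = render(scene, [exp["band"]], intr, pose,
                      TransportConfig(seed=2))
        img = prod.band_images["sw"]
        # plate fills the whole 30 deg view from 1 m: every pixel exact
        np.testing.assert_allclose(img, exp["camera_pixel"], rtol=1e-12)

    def test_black_scene_renders_zero(self):
        scene, exp = generate_fixture("single_plate")
        scene.materials["plate"].band_overrides["sw"] = (0.0, 0.0)
        intr, pose = down_camera(res=9, z=1.0, spp=4)
        prod = render(scene, [exp["band"]], intr, pose,
                      TransportConfig(seed=2))
        assert np.all(prod.band_images["sw"] == 0.0)

    def test_same_seed_bitwise_identical_product(self):
        scene, exp = generate_fixture("mini_canopy", seed=4)
        intr, pose = down_camera(res=16, z=1.8, hfov_deg=50, spp=2)
        cfg = TransportConfig(seed=11, rays_per_primitive_direct=4,
                              rays_per_primitive_diffuse=2,
                              max_scattering_iterations=3,
                              default_temperature=295.0)
        a = render(scene, exp["bands"], intr, pose, cfg, with_depth=True)
        scene2, _ = generate_fixture("mini_canopy", seed=4)
        b = render(scene2, exp["bands"], intr, pose, cfg, with_depth=True)
        for k in a.band_images:
            np.testing.assert_array_equal(a.band_images[k], b.band_images[k])
        np.testing.assert_array_equal(a.depth_map, b.depth_map)

    def test_sky_pixels_read_sky_radiance(self):
        scene, exp = generate_fixture("single_plate")
        intr, pose = down_camera(res=9, z=1.0, hfov_deg=120, spp=4)
        prod = render(scene, [exp["band"]], intr, pose,
                      TransportConfig(seed=2), sky_radiance={"sw": 55.0})
        corner = prod.band_images["sw"][0, 0]    # far outside the 1 m plate
        assert corner == pytest.approx(55.0)


class TestAnnotation:
    def test_occlusion_nearest_wins(self, intersection_oracle):
        scene, exp = generate_fixture("occlusion_pair")
        intr, pose = down_camera(res=21, z=3.0, hfov_deg=45)
        label = annotate(scene, intr, pose, "plant_id", background=-1)
        depth = depth_image(scene, intr, pose)
        thermal = thermal_image(scene, intr, pose)
        from phytoray.camera import _center_rays

        O, D = _center_rays(intr, pose)
        for i in range(O.shape[0]):
            j, t, _ = intersection_oracle(scene, O[i], D[i])
            r, c = divmod(i, 21)
            if j < 0:
                assert label[r, c] == -1
                assert np.isinf(depth[r, c])
            else:
                p = scene.primitives[j]
                assert label[r, c] == p.data["plant_id"]
                assert depth[r, c] == pytest.approx(t, abs=1e-9)
                assert thermal[r, c] == p.data["temperature"]

    def test_empty_scene_all_background(self):
        sc = Scene([make_patch((0, 0, -50), (0.01, 0.01), uid=0,
                               data={"plant_id": 1})])
        intr, pose = down_camera(res=5, z=1.0)
        label = annotate(Scene([]), intr, pose, "plant_id",
                         background=-7) if False else \
            annotate(sc, intr, pose, "plant_id", background=-7)
        # the far tiny plate covers (at most) the very centre; corners miss
        assert label[0, 0] == -7

    def test_center_pixel_depth_exact(self):
        sc = Scene([make_patch((0, 0, 0), (10, 10), uid=0)])
        intr, pose = down_camera(res=33, z=5.0)
        depth = depth_image(sc, intr, pose)
        assert depth[16, 16] == pytest.approx(5.0, abs=1e-12)

    def test_oblique_plate_depth_matches_ray_plane_closed_form(self):
        rot = (0.3, 0.0, 0.0)
        sc = Scene([make_patch((0, 0, 0), (40, 40), rotation=rot, uid=0)])
        intr, pose = down_camera(res=11, z=4.0, hfov_deg=30)
        depth = depth_image(sc, intr, pose)
        from phytoray.camera import _center_rays
        from phytoray.geometry import rotation_matrix

        O, D = _center_rays(intr, pose)
        n = rotation_matrix(*rot) @ [0, 0, 1]
        t = -(O @ n) / (D @ n)
        np.testing.assert_allclose(depth, t.reshape(11, 11), atol=1e-9)

    def test_thermal_emitted_flux_mode(self):
        sc = Scene([make_patch((0, 0, 0), (10, 10), uid=0, emissivity=0.9,
                               data={"temperature": 310.0})])
        intr, pose = down_camera(res=5, z=2.0)
        img = thermal_image(sc, intr, pose, mode="emitted_flux")
        assert img[2, 2] == pytest.approx(0.9 * SIGMA_SB * 310.0 ** 4)

    def test_missing_key_warns_and_uses_background(self):
        sc = Scene([make_patch((0, 0, 0), (10, 10), uid=0)])
        intr, pose = down_camera(res=5, z=2.0)
        with pytest.warns(UserWarning, match="lacking"):
            label = annotate(sc, intr, pose, "plant_id", background=-2)
        assert np.all(label == -2)


class TestDefocus:
    @staticmethod
    def _edge_width(lens_diameter):
        """10-90% transition width (px) of a vertical edge off the focal
        plane: plate at 2 m, focus at 0.5 m."""
        mat = Material("m", band_overrides={"sw": (0.5, 0.0)})
        # plate occupies y < 0 exactly (edge through the optical axis)
        plate = make_patch((0, -25.0, 0), (50.0, 50.0), uid=0,
                           material_front="m")
        sun = RadiationSource("collimated_sun", direction=[0, 0, 1],
                              band_fluxes={"sw": 1000.0})
        sc = Scene([plate], {"m": mat}, [sun])
        intr = CameraIntrinsics(hfov=np.deg2rad(30), resolution=(48, 48),
                                lens_diameter=lens_diameter,
                                focal_plane_distance=0.5,
                                samples_per_pixel=96)
        pose = CameraPose([0, 0, 2.0], [0, 0, -1], up_hint=[0, 1, 0])
        prod = render(sc, [WaveBand("sw", 400, 700)], intr, pose,
                      TransportConfig(seed=8))
        profile = prod.band_images["sw"].mean(axis=1)     # along the edge
        profile = profile / profile.max()                 # increasing 0 -> 1
        x = np.arange(profile.size)
        lo = np.interp(0.1, profile, x)
        hi = np.interp(0.9, profile, x)
        return hi - lo

    def test_pinhole_edge_is_sharp(self):
        assert self._edge_width(1e-6) <= 1.0

    def test_blur_grows_with_lens_diameter(self):
        w = [self._edge_width(d) for d in (1e-6, 0.005, 0.02)]
        assert w[0] < w[1] < w[2]


class TestDistortion:
    def test_zero_coefficients_bitwise_identity(self, rng):
        img = rng.random((37, 53))
        out = apply_distortion(img, DistortionCoefficients())
        np.testing.assert_array_equal(out, img)

    def test_center_pixel_never_moves(self):
        c = DistortionCoefficients(p1=1e-4, p2=1e-8, p3=1e-4, p4=1e-4)
        assert distortion_shift(0.0, 0.0, c) == (0.0, 0.0)

    def test_spot_value_radial(self):
        c = DistortionCoefficients(p1=1e-6)
        du, dv = distortion_shift(100.0, 0.0, c)
        assert du == pytest.approx(1.0) and dv == 0.0

    def test_spot_value_tangential(self):
        c = DistortionCoefficients(p3=1e-5)
        du, dv = distortion_shift(10.0, 20.0, c)
        assert du == pytest.approx(2 * 1e-5 * 10 * 20)
        assert dv == pytest.approx(1e-5 * (500 + 2 * 400))

    def test_barrel_parameters_open_border_gaps(self):
        img = np.ones((64, 64))
        out = apply_distortion(img, DistortionCoefficients(p1=-2e-5),
                               background=0.0)
        border = np.concatenate([out[0], out[-1], out[:, 0], out[:, -1]])
        assert (border == 0.0).sum() > 0

    def test_label_maps_are_remapped_like_images(self):
        labels = np.zeros((32, 32))
        labels[10:20, 10:20] = 5.0
        out = apply_distortion(labels, DistortionCoefficients(p1=-4e-5),
                               background=-1.0)
        assert set(np.unique(out)) <= {-1.0, 0.0, 5.0}   # no blending
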