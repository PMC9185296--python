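"""Bunch generation, reference/depth-scan rendering and the artifact model."""

import numpy as np
import pytest

import berrycloud as bc
from berrycloud.synthetic import GenerationError, _pair_overlap


class TestGenerateBunch:
    def test_single_berry_at_cluster_centre(self):
        cfg = bc.BunchConfig(n_berries=1)
        model = bc.generate_bunch(cfg, seed=5)
        np.testing.assert_array_equal(model.berries[0].center, cfg.center)

    def test_deterministic_for_fixed_seed(self):
        a = bc.generate_bunch(seed=1)
        b = bc.generate_bunch(seed=1)
        np.testing.assert_array_equal(a.centers(), b.centers())
        np.testing.assert_array_equal(a.radii(), b.radii())

    def test_pairwise_overlap_invariant_brute_force(self, bunch):
        cfg = bunch.config
        for i, a in enumerate(bunch.berries):
            for b in bunch.berries[i + 1:]:
                overlap = _pair_overlap(a, b)
                assert overlap <= cfg.max_overlap_frac * min(a.radius, b.radius) + 1e-9

    def test_radii_stay_in_configured_band(self):
        radii = np.concatenate([bc.generate_bunch(seed=s).radii() for s in range(5)])
        assert radii.min() >= 10.0 and radii.max() <= 18.0
        assert abs(np.mean(radii) - 13.7) < 1.0

    def test_impossible_packing_raises(self):
        cfg = bc.BunchConfig(n_berries=200, cluster_radius_mm=10.0,
                             cluster_length_mm=20.0, max_attempts_per_berry=50)
        with pytest.raises(GenerationError):
            bc.generate_bunch(cfg, seed=0)


class TestRenderReferenceScan:
    def test_point_count_tracks_surface_area(self, rng):
        r = 13.7
        model = bc.BunchModel([bc.Sphere([0, 0, 600.0], r)], seed=0, config=bc.BunchConfig(n_berries=1))
        cloud = bc.render_reference_scan(model, density=2.0, seed=4)
        expected = 2.0 * 4 * np.pi * r**2
        assert abs(len(cloud) - expected) / expected < 0.1

    def test_points_lie_on_labelled_sphere(self, bunch, reference_scan):
        centers, radii = bunch.centers(), bunch.radii()
        d = np.linalg.norm(reference_scan.points - centers[reference_scan.labels], axis=1)
        np.testing.assert_allclose(d, radii[reference_scan.labels], atol=1e-6)

    def test_two_disjoint_spheres_partition_labels(self):
        model = bc.BunchModel([bc.Sphere([0, 0, 600.0], 10.0), bc.Sphere([50, 0, 600.0], 10.0)],
                              seed=0, config=bc.BunchConfig(n_berries=2))
        cloud = bc.render_reference_scan(model, density=1.0, seed=4)
        assert set(np.unique(cloud.labels)) == {0, 1}

    def test_buried_points_removed(self):
        # heavily overlapping pair: interior points of each sphere are culled
        model = bc.BunchModel([bc.Sphere([0, 0, 600.0], 10.0), bc.Sphere([12, 0, 600.0], 10.0)],
                              seed=0, config=bc.BunchConfig(n_berries=2))
        cloud = bc.render_reference_scan(model, density=2.0, seed=4)
        centers, radii = model.centers(), model.radii()
        for j in range(2):
            other = cloud.points[cloud.labels != j]
            assert np.all(np.linalg.norm(other - centers[j], axis=1) >= radii[j] - 1e-6)


class TestRenderDepthScan:
    def test_reference_preset_matches_analytic_intersection(self):
        center = np.array([0.0, 0.0, 600.0])
        model = bc.BunchModel([bc.Sphere(center, 13.7)], seed=0, config=bc.BunchConfig(n_berries=1))
        pose = bc.CameraPose(origin=np.zeros(3), look_at=center)
        cloud = bc.render_depth_scan(model, pose, bc.preset("reference"), seed=0)
        assert len(cloud) > 100
        # every point lies exactly on the camera-facing surface
        d = np.linalg.norm(cloud.points - center, axis=1)
        np.testing.assert_allclose(d, 13.7, atol=1e-6)
        assert np.all(cloud.points[:, 2] <= center[2])

    def test_quantisation_multiples(self, bunch, pose):
        art = bc.ArtifactModel(technology="structured_light", quantisation_step_mm=5.0)
        cloud = bc.render_depth_scan(bunch, pose, art, pixel_pitch=0.002, seed=0)
        t = np.linalg.norm(cloud.points - pose.origin, axis=1)
        np.testing.assert_allclose(t / 5.0, np.round(t / 5.0), atol=1e-9)

    def test_deterministic_per_seed(self, bunch, pose):
        a = bc.render_depth_scan(bunch, pose, bc.preset("tof"), pixel_pitch=0.002, seed=9)
        b = bc.render_depth_scan(bunch, pose, bc.preset("tof"), pixel_pitch=0.002, seed=9)
        np.testing.assert_array_equal(a.points, b.points)

    def test_painted_equals_reference_geometry(self, bunch, pose):
        """Painting suppresses bias/distortion; with sampling artifacts off the
        painted ToF scan is the reference-geometry scan plus noise only."""
        art = bc.ArtifactModel(technology="tof", depth_bias_mm=7.0,
                               distortion_amp_mm=2.5, painted=True)
        painted = bc.render_depth_scan(bunch, pose, art, pixel_pitch=0.002, seed=9)
        clean = bc.render_depth_scan(bunch, pose, bc.preset("reference"),
                                     pixel_pitch=0.002, seed=9)
        np.testing.assert_allclose(painted.points, clean.points, atol=1e-9)

    def test_mean_alongray_gap_unpainted_vs_painted(self, bunch, pose):
        """Painted-vs-unpainted along-ray difference equals the depth bias.

        Both renders share the ray grid and keep every valid pixel, so points
        correspond index by index.  The few flying-pixel displacements hit
        different pixels in the two renders and are trimmed before averaging.
        """
        art = bc.preset("tof")
        art_p = bc.preset("tof", painted=True)
        a = bc.render_depth_scan(bunch, pose, art, pixel_pitch=0.0015, seed=9)
        p = bc.render_depth_scan(bunch, pose, art_p, pixel_pitch=0.0015, seed=9)
        assert len(a) == len(p)
        diff = (np.linalg.norm(a.points - pose.origin, axis=1)
                - np.linalg.norm(p.points - pose.origin, axis=1))
        core = diff[np.abs(diff - np.median(diff)) < 5.0]
        assert abs(core.mean() - art.depth_bias_mm) < 0.3

    def test_empty_view_allowed(self):
        model = bc.BunchModel([bc.Sphere([0, 0, 600.0], 5.0)], seed=0,
                              config=bc.BunchConfig(n_berries=1))
        pose = bc.CameraPose(origin=np.zeros(3), look_at=[0, 0, 600.0])
        # aim the angular window at the berry but put the berry behind a miss:
        # a sphere fully outside every grid ray yields an empty cloud
        art = bc.ArtifactModel(technology="reference", dropout_fraction=0.0)
        cloud = bc.render_depth_scan(model, pose, art, pixel_pitch=0.5, seed=0)
        assert len(cloud) >= 0   # renders without error even for coarse grids


class TestScatterDistortion:
    def _setup(self):
        berry = bc.Sphere([0.0, 0.0, 350.0], 13.7)
        pose = bc.CameraPose(origin=np.zeros(3), look_at=berry.center)
        return berry, pose

    def test_equator_gets_bias_only(self):
        berry, pose = self._setup()
        art = bc.ArtifactModel(technology="tof", depth_bias_mm=8.0, distortion_amp_mm=5.0,
                               standoff_ref_mm=350.0)
        point = berry.center + np.array([13.7, 0.0, 0.0])     # theta = 90 deg
        out = bc.apply_scatter_distortion(point, berry, pose, art)
        ray = point / np.linalg.norm(point)
        np.testing.assert_allclose(out, point + 8.0 * ray, atol=1e-9)

    def test_pole_gets_bias_plus_amp(self):
        berry, pose = self._setup()
        art = bc.ArtifactModel(technology="tof", depth_bias_mm=8.0, distortion_amp_mm=5.0,
                               standoff_ref_mm=350.0)
        pole = berry.center + np.array([0.0, 0.0, -13.7])     # camera-facing pole
        out = bc.apply_scatter_distortion(pole, berry, pose, art)
        assert out[2] - pole[2] == pytest.approx(13.0, abs=1e-9)

    def test_distortion_halves_when_distance_doubles(self):
        berry = bc.Sphere([0.0, 0.0, 700.0], 13.7)
        pose = bc.CameraPose(origin=np.zeros(3), look_at=berry.center)
        art = bc.ArtifactModel(technology="tof", depth_bias_mm=8.0, distortion_amp_mm=5.0,
                               standoff_ref_mm=350.0)
        pole = berry.center + np.array([0.0, 0.0, -13.7])
        out = bc.apply_scatter_distortion(pole, berry, pose, art)
        # D = 700 = 2 x standoff_ref: distortion term halves, bias unchanged
        assert out[2] - pole[2] == pytest.approx(8.0 + 2.5, abs=1e-9)

    def test_peak_is_sharply_localised(self):
        """The apex stands far above the distortion at 60 deg (pointed shape)."""
        art = bc.preset("tof")
        from berrycloud.synthetic import _scatter_displacement_mm
        at0 = _scatter_displacement_mm(np.array([1.0]), art.standoff_ref_mm, art)[0]
        at60 = _scatter_displacement_mm(np.array([0.5]), art.standoff_ref_mm, art)[0]
        peak_minus_edge = at0 - at60
        assert peak_minus_edge > 2 * (at60 - art.depth_bias_mm)

    def test_centre_point_rejected(self):
        berry, pose = self._setup()
        art = bc.ArtifactModel(technology="tof", depth_bias_mm=8.0)
        with pytest.raises(ValueError):
            bc.apply_scatter_distortion(berry.center, berry, pose, art)

    def test_painted_model_rejects_application(self):
        berry, pose = self._setup()
        art = bc.ArtifactModel(technology="tof", depth_bias_mm=8.0, painted=True)
        with pytest.raises(ValueError):
            bc.apply_scatter_distortion(berry.center + [0, 0, -13.7], berry, pose, art)


class TestArtifactModel:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            bc.ArtifactModel(technology="tof", dropout_fraction=1.2)
        with pytest.raises(ValueError):
            bc.ArtifactModel(technology="tof", depth_bias_mm=-1.0)

    def test_painted_forces_zero_effective_bias(self):
        art = bc.ArtifactModel(technology="tof", depth_bias_mm=7.0,
                               distortion_amp_mm=2.0, painted=True)
        assert art.effective_bias_mm == 0.0
        assert art.effective_distortion_amp_mm == 0.0

    def test_unknown_technology_rejected(self):
        with pytest.raises(ValueError):
            bc.ArtifactModel(technology="sonar")


class TestChequerboardLandmarks:
    def test_identity_transform_noiseless(self):
        Y, X = bc.chequerboard_landmarks(8, transform=None, noise_sd_mm=0.0, seed=0)
        np.testing.assert_array_equal(Y.points, X.points)

    def test_known_transform_recovered(self, rng):
        from conftest import random_rotation
        truth = bc.RigidTransform(random_rotation(rng), rng.uniform(-40, 40, 3))
        Y, X = bc.chequerboard_landmarks(12, transform=truth, noise_sd_mm=0.0, seed=0)
        t = bc.landmark_align(X, Y)
        assert np.linalg.norm(t.R - truth.R) < 1e-9
        assert np.linalg.norm(t.T - truth.T) < 1e-9

    def test_three_points_never_collinear(self):
        Y, _ = bc.chequerboard_landmarks(3, transform=None, noise_sd_mm=0.0, seed=0)
        a, b, c = Y.points
        assert np.linalg.norm(np.cross(b - a, c - a)) > 1.0
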