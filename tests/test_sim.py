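"""Synthetic scene, kinetics, and rendering generators."""

import numpy as np
import pytest

from paintkit import sim


class TestClutchScene:
    def test_empty_scene_forbidden(self):
        with pytest.raises(ValueError):
            sim.make_clutch_scene(0, 10, 50.0, (5000.0, 5000.0), seed=0)

    def test_fov_too_small_for_sigma(self):
        with pytest.raises(ValueError):
            sim.make_clutch_scene(1, 10, 1000.0, (2000.0, 2000.0), seed=0)

    def test_single_cluster_covariance(self):
        scene = sim.make_clutch_scene(1, 100, 50.0, (5000.0, 5000.0), seed=3)
        eig = np.linalg.eigvalsh(np.cov(scene.sites.T))
        assert np.all(np.abs(eig - 2500.0) < 0.3 * 2500.0)

    def test_many_clusters_counts(self):
        scene = sim.make_clutch_scene(1000, 20, 50.0, (200000.0, 200000.0), seed=4)
        assert scene.n_sites == 20000
        assert scene.n_structures == 1000
        assert np.array_equal(np.unique(scene.structure_ids), np.arange(1000))

    def test_sites_inside_fov(self):
        scene = sim.make_clutch_scene(50, 30, 80.0, (6000.0, 6000.0), seed=5)
        assert np.all(scene.sites >= 0)
        assert np.all(scene.sites <= [6000.0, 6000.0])


class TestTubeScene:
    def test_zero_drift_is_static(self):
        scene = sim.make_tube_scene(3, 50.0, 100, drift_speed=0.0,
                                    fov=(10000.0, 10000.0), seed=1)
        assert np.allclose(scene.motion(57.3), 0.0)
        assert np.allclose(scene.positions_at(10.0), scene.sites)

    def test_straight_tube_transverse_spread(self):
        ctrl = np.column_stack([np.linspace(1000, 9000, 5), np.full(5, 5000.0)])
        scene = sim.make_tube_scene(1, 75.0, 2000, fov=(10000.0, 10000.0),
                                    seed=2, control_points=[ctrl])
        sd_y = scene.sites[:, 1].std()
        assert abs(sd_y - 75.0) < 0.25 * 75.0

    def test_drift_displacement_magnitude(self):
        scene = sim.make_tube_scene(20, 50.0, 10, drift_speed=10.0,
                                    fov=(20000.0, 20000.0), seed=3)
        disp = scene.motion(100.0)
        mags = np.hypot(disp[:, 0], disp[:, 1])
        assert abs(mags.mean() - 1000.0) < 0.3 * 1000.0


class TestBinding:
    def test_zero_on_rate_gives_no_events(self, clutch_scene):
        kin = sim.KineticsParams(site_on_rate=0.0, duration=10.0)
        trace = sim.simulate_binding(clutch_scene, kin, seed=0)
        assert trace.n_events == 0

    def test_poisson_event_count(self):
        scene = sim.make_clutch_scene(5, 20, 50.0, (5000.0, 5000.0), seed=1)
        kin = sim.KineticsParams(site_on_rate=0.1, duration=100.0)
        trace = sim.simulate_binding(scene, kin, seed=7)
        expected = 100 * 0.1 * 100.0  # 100 sites x rate x duration
        assert abs(trace.n_events - expected) < 3 * np.sqrt(expected)

    def test_residence_time_mean_recovery(self, clutch_scene):
        kin = sim.KineticsParams(site_on_rate=0.1, mean_residence=0.1, duration=100.0)
        trace = sim.simulate_binding(clutch_scene, kin, seed=8)
        assert trace.n_events >= 1000
        assert abs(trace.duration.mean() - 0.1) < 0.1 * 0.1

    def test_events_sorted_by_start(self, clutch_scene, clutch_kinetics):
        trace = sim.simulate_binding(clutch_scene, clutch_kinetics, seed=9)
        assert np.all(np.diff(trace.start) >= 0)

    def test_seed_determinism(self, clutch_scene, clutch_kinetics):
        t1 = sim.simulate_binding(clutch_scene, clutch_kinetics, seed=5)
        t2 = sim.simulate_binding(clutch_scene, clutch_kinetics, seed=5)
        assert np.array_equal(t1.start, t2.start)
        assert np.array_equal(t1.duration, t2.duration)


class TestEventsToLocalizations:
    def _one_event(self, duration, start=0.0):
        scene = sim.GroundTruthScene(np.array([[500.0, 500.0]]), [0], (1000.0, 1000.0))
        trace = sim.BindingEventTrace([0], [start], [duration])
        return scene, trace

    def test_full_frame_coverage_count(self):
        scene, trace = self._one_event(0.2 - 1e-9)
        kin = sim.KineticsParams(duration=1.0, exposure=0.05)
        table = sim.events_to_localizations(scene, trace, kin, 0.0, seed=0)
        assert len(table) == 4
        assert np.array_equal(table.df["frame"].to_numpy(), [1, 2, 3, 4])

    def test_noiseless_positions_exact(self):
        scene, trace = self._one_event(0.5)
        kin = sim.KineticsParams(duration=1.0, exposure=0.05)
        table = sim.events_to_localizations(scene, trace, kin, 0.0, seed=0)
        assert np.allclose(table.xy, [500.0, 500.0])

    def test_rms_radial_error_matches_precision(self):
        scene = sim.GroundTruthScene(np.array([[5000.0, 5000.0]]), [0], (10000.0, 10000.0))
        trace = sim.BindingEventTrace([0], [0.0], [100.0])
        kin = sim.KineticsParams(duration=100.0, exposure=0.05)
        table = sim.events_to_localizations(scene, trace, kin, 20.0, seed=1)
        assert len(table) >= 1000
        radial = np.hypot(table.xy[:, 0] - 5000.0, table.xy[:, 1] - 5000.0)
        rms = np.sqrt(np.mean(radial**2))
        assert abs(rms - 20.0 * np.sqrt(2)) < 0.1 * 20.0 * np.sqrt(2)

    def test_conservation_of_localization_count(self, clutch_scene, clutch_kinetics):
        trace = sim.simulate_binding(clutch_scene, clutch_kinetics, seed=2)
        table = sim.events_to_localizations(clutch_scene, trace, clutch_kinetics,
                                            20.0, seed=3)
        expected = 0
        for i in range(trace.n_events):
            frames, frac = sim.event_frame_overlaps(
                trace.start[i], trace.duration[i], clutch_kinetics.exposure,
                clutch_kinetics.n_frames)
            expected += int(np.sum(frac >= 0.5))
        assert len(table) == expected

    def test_localization_rate_scaling(self, clutch_scene, clutch_kinetics):
        trace = sim.simulate_binding(clutch_scene, clutch_kinetics, seed=4)
        table = sim.events_to_localizations(clutch_scene, trace, clutch_kinetics,
                                            20.0, seed=5)
        observed_rate = len(table) / clutch_kinetics.duration
        expected = sim.expected_localization_rate(clutch_scene.n_sites, clutch_kinetics)
        assert abs(observed_rate - expected) < 0.2 * expected

    def test_touch_all_counting_matches_classic_formula(self, clutch_scene):
        # with no overlap threshold the mean frames/event is tau/exposure + 1
        kin = sim.KineticsParams(site_on_rate=0.05, mean_residence=0.1, duration=100.0)
        trace = sim.simulate_binding(clutch_scene, kin, seed=6)
        table = sim.events_to_localizations(clutch_scene, trace, kin, 20.0,
                                            seed=7, min_overlap=1e-12)
        expected = sim.expected_localization_rate(clutch_scene.n_sites, kin,
                                                  min_overlap=0.0)
        assert abs(len(table) / kin.duration - expected) < 0.2 * expected


class TestRenderStack:
    def test_paper_frame_count_200s(self):
        kin = sim.KineticsParams(duration=200.0, exposure=0.05)
        assert kin.n_frames == 4000

    def test_empty_trace_background_only(self):
        scene = sim.GroundTruthScene(np.array([[500.0, 500.0]]), [0], (1000.0, 1000.0))
        trace = sim.BindingEventTrace(np.empty(0, int), np.empty(0), np.empty(0))
        kin = sim.KineticsParams(duration=0.5, exposure=0.05)
        cam = sim.CameraModel(100.0, 150.0, background_rate=10.0, frame_shape=(16, 16))
        stack = sim.render_stack(scene, trace, kin, cam, seed=0)
        assert stack.shape == (10, 16, 16)
        assert abs(stack.mean() - 10.0) < 3 * np.sqrt(10.0 / stack.size)

    def test_photon_conservation_single_event(self):
        scene = sim.GroundTruthScene(np.array([[1600.0, 1600.0]]), [0], (3200.0, 3200.0))
        trace = sim.BindingEventTrace([0], [0.0], [0.05 - 1e-9])
        kin = sim.KineticsParams(photon_rate=20000.0, duration=0.05, exposure=0.05)
        cam = sim.CameraModel(100.0, 150.0, background_rate=0.0, frame_shape=(32, 32))
        stack = sim.render_stack(scene, trace, kin, cam, seed=1)
        n_expected = 20000.0 * 0.05
        assert abs(stack[0].sum() - n_expected) < 3 * np.sqrt(n_expected)

    def test_camera_must_cover_fov(self):
        scene = sim.GroundTruthScene(np.array([[500.0, 500.0]]), [0], (9000.0, 9000.0))
        trace = sim.BindingEventTrace([0], [0.0], [0.1])
        kin = sim.KineticsParams(duration=0.5)
        cam = sim.CameraModel(100.0, 150.0, frame_shape=(16, 16))
        with pytest.raises(ValueError):
            sim.render_stack(scene, trace, kin, cam, seed=0)

    def test_stack_seed_determinism(self):
        scene = sim.make_clutch_scene(3, 5, 40.0, (1600.0, 1600.0), seed=0)
        kin = sim.KineticsParams(site_on_rate=0.5, duration=0.5)
        trace = sim.simulate_binding(scene, kin, seed=1)
        cam = sim.CameraModel(100.0, 150.0, frame_shape=(16, 16))
        s1 = sim.render_stack(scene, trace, kin, cam, seed=2)
        s2 = sim.render_stack(scene, trace, kin, cam, seed=2)
        assert np.array_equal(s1, s2)
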