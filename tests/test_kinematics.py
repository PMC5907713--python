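"""Kinematics oracles: centroid geometry, SG differentiation against analytic
derivatives, Procrustes pose recovery, frame transformation and events."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitclust.config import RunConfig
from gaitclust.io_formats import EventTable, TrajectoryTable
from gaitclust.kinematics import (
    detect_events,
    double_differentiate,
    estimate_pose,
    global_to_local,
    pelvic_centroid,
    pose_series,
    sg_derivative,
    vertical_excursion,
)

DT = 0.005


class TestPelvicCentroid:
    def test_single_marker_is_identity(self):
        pos = np.random.default_rng(0).normal(size=(20, 1, 3))
        table = TrajectoryTable.from_arrays(pos, ["M0"], DT)
        np.testing.assert_allclose(pelvic_centroid(table), pos[:, 0], atol=1e-12)

    def test_cube_corners_give_center(self):
        corners = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
             [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]], float
        )
        center = np.array([10.0, -5.0, 2.0])
        pos = np.broadcast_to(corners + center - 0.5, (15, 8, 3)).copy()
        table = TrajectoryTable.from_arrays(pos, [f"M{i}" for i in range(8)], DT)
        np.testing.assert_allclose(
            pelvic_centroid(table), np.broadcast_to(center, (15, 3)), atol=1e-9
        )

    def test_noise_free_subject_matches_construction(self, noise_free_subject):
        """Centroid of the rigid zero-mean cluster equals the pelvis origin."""
        cen = pelvic_centroid(noise_free_subject.dynamic)
        pos = noise_free_subject.dynamic.positions()
        np.testing.assert_allclose(cen, pos.mean(axis=1), atol=1e-9)


class TestSgDerivative:
    def test_constant_gives_zero(self):
        d = sg_derivative(np.full(100, 3.7), DT)
        assert np.nanmax(np.abs(d)) < 1e-10

    def test_cubic_is_exact(self):
        t = np.arange(200) * DT
        d = sg_derivative(t**3, DT, window=11, order=4)
        valid = np.isfinite(d)
        np.testing.assert_allclose(d[valid], 3 * t[valid] ** 2, atol=1e-9)

    def test_sine_matches_analytic_derivative(self):
        t = np.arange(2000) * DT
        x = np.sin(2 * np.pi * 3 * t)
        d = sg_derivative(x, DT)
        expect = 6 * np.pi * np.cos(2 * np.pi * 3 * t)
        valid = np.isfinite(d)
        err = np.max(np.abs(d[valid] - expect[valid])) / np.max(np.abs(expect))
        assert err < 0.01

    def test_even_window_supported(self):
        t = np.arange(200) * DT
        d = sg_derivative(t**2, DT, window=10, order=4)
        valid = np.isfinite(d)
        # evaluation at the half-sample-shifted centre: derivative of t^2
        expect = 2 * (t + 0.5 * DT)
        np.testing.assert_allclose(d[valid], expect[valid], atol=1e-8)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sg_derivative(np.zeros(5), DT, window=11)


class TestDoubleDifferentiate:
    def test_quadratic_gives_constant_acceleration(self):
        t = np.arange(300) * DT
        a = np.array([1.0, 2.0, 3.0])
        pos_mm = 0.5 * a * t[:, None] ** 2 * 1000.0
        acc = double_differentiate(pos_mm, DT)
        np.testing.assert_allclose(
            acc.data[acc.valid], np.broadcast_to(a, (acc.valid.sum(), 3)), atol=1e-6
        )

    @pytest.mark.parametrize("freq", [1.0, 3.0, 5.0])
    def test_sinusoid_matches_analytic_second_derivative(self, freq):
        t = np.arange(3000) * DT
        A = 0.02  # 20 mm
        omega = 2 * np.pi * freq
        pos_mm = np.zeros((len(t), 3))
        pos_mm[:, 2] = A * np.sin(omega * t) * 1000.0
        acc = double_differentiate(pos_mm, DT)
        expect = -A * omega**2 * np.sin(omega * t)
        err = np.sqrt(np.mean((acc.data[acc.valid, 2] - expect[acc.valid]) ** 2))
        assert err < 0.02 * np.sqrt(np.mean(expect**2))

    def test_polynomial_exact_to_fit_order(self):
        t = np.arange(300) * DT
        pos_mm = (t**4 - 2 * t**3 + t)[:, None] * 1000.0 * np.ones(3)
        acc = double_differentiate(pos_mm, DT)
        expect = 12 * t**2 - 12 * t
        np.testing.assert_allclose(
            acc.data[acc.valid, 0], expect[acc.valid], atol=1e-5
        )


class TestEstimatePose:
    def test_identity_for_static_frame(self):
        markers = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], float)
        pose = estimate_pose(markers, markers)
        np.testing.assert_allclose(pose.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(pose.translation, 0, atol=1e-12)
        assert pose.residual == pytest.approx(0, abs=1e-12)

    def test_ninety_degree_yaw_recovered(self):
        static = np.array([[100, 0, 0], [0, 100, 0], [-100, 0, 0], [0, -100, 20]], float)
        R_true = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        frame = static @ R_true.T + np.array([5.0, -3.0, 2.0])
        pose = estimate_pose(frame, static)
        np.testing.assert_allclose(pose.rotation, R_true, atol=1e-10)
        np.testing.assert_allclose(pose.translation, [5, -3, 2], atol=1e-9)
        assert pose.residual < 1e-9

    def test_noisy_frame_recovered_within_half_degree(self, rng):
        static = np.array(
            [[75, 60, -5], [75, -60, -5], [-75, 85, 15], [-75, -85, -5]], float
        )
        R_true = Rotation.from_euler("zx", [7.0, -4.0], degrees=True).as_matrix()
        frame = static @ R_true.T + rng.normal(0, 0.5, size=static.shape)
        pose = estimate_pose(frame, static)
        assert pose.residual > 0
        err = Rotation.from_matrix(pose.rotation.T @ R_true).magnitude()
        assert np.degrees(err) < 0.5

    def test_collinear_markers_rejected(self):
        static = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            estimate_pose(static, static)

    def test_rotations_are_proper_every_frame(self, noisy_subject):
        R = pose_series(
            noisy_subject.dynamic.positions(),
            noisy_subject.static.positions().mean(axis=0),
        )
        dets = np.linalg.det(R)
        np.testing.assert_allclose(dets, 1.0, atol=1e-9)
        eye = np.einsum("nij,nik->njk", R, R)
        np.testing.assert_allclose(eye, np.broadcast_to(np.eye(3), eye.shape), atol=1e-9)


class TestGlobalToLocal:
    def _series(self, data):
        n = data.shape[0]
        valid = np.ones(n, bool)
        from gaitclust.kinematics import AccelerationSeries

        return AccelerationSeries(
            time=np.arange(n) * DT, data=data, frame_label="global", valid=valid
        )

    def test_no_rotation_is_identity(self, rng):
        static = np.array([[1, 0, 0.0], [0, 1, 0], [0, 0, 1], [1, 1, 0]]) * 100
        dyn = np.broadcast_to(static + [0, 0, 5.0], (50, 4, 3)).copy()
        acc = self._series(rng.normal(size=(50, 3)))
        local = global_to_local(acc, dyn, static)
        np.testing.assert_allclose(local.data, acc.data, atol=1e-9)

    def test_constant_yaw_swaps_horizontal_axes(self):
        static = np.array([[100, 0, 0.0], [0, 100, 0], [-100, 0, 0], [0, -100, 20]])
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        dyn = np.broadcast_to(static @ R.T, (50, 4, 3)).copy()
        a_global = np.tile([1.0, 2.0, 3.0], (50, 1))
        local = global_to_local(self._series(a_global), dyn, static)
        # a_local = R^T a_global: x' = y, y' = -x, z unchanged
        np.testing.assert_allclose(
            local.data, np.tile([2.0, -1.0, 3.0], (50, 1)), atol=1e-9
        )

    def test_noise_free_subject_recovers_truth(self, noise_free_subject):
        """End-to-end oracle: centroid double differentiation + frame
        transformation reproduces the generator's local acceleration."""
        cen = pelvic_centroid(noise_free_subject.dynamic)
        acc = double_differentiate(cen, DT)
        local = global_to_local(
            acc, noise_free_subject.dynamic, noise_free_subject.static
        )
        v = local.valid
        truth = noise_free_subject.truth_local_acc
        err = np.sqrt(np.mean((local.data[v] - truth[v]) ** 2))
        assert err < 0.02 * np.sqrt(np.mean(truth[v] ** 2))


class TestDetectEvents:
    def _local_acc(self, trial):
        cen = pelvic_centroid(trial.dynamic)
        acc = double_differentiate(cen, DT)
        return global_to_local(acc, trial.dynamic, trial.static)

    def test_strikes_match_truth_within_10ms(self, noisy_subject):
        local = self._local_acc(noisy_subject)
        detected = detect_events(local, RunConfig())
        det = detected.data["foot_strike_frame"].to_numpy()
        truth = noisy_subject.events.data["foot_strike_frame"].to_numpy()
        matched = sum(np.min(np.abs(det - s)) <= 2 for s in truth)
        assert matched / len(truth) >= 0.95

    def test_flat_signal_rejected(self):
        from gaitclust.kinematics import AccelerationSeries

        n = 2000
        flat = AccelerationSeries(
            time=np.arange(n) * DT,
            data=np.zeros((n, 3)),
            frame_label="local",
            valid=np.ones(n, bool),
        )
        with pytest.raises(ValueError, match="periodic"):
            detect_events(flat, RunConfig())

    def test_supplied_events_passthrough(self, noisy_subject):
        local = self._local_acc(noisy_subject)
        out = detect_events(local, RunConfig(), events=noisy_subject.events)
        assert out is noisy_subject.events


class TestVerticalExcursion:
    def test_sinusoid_peak_to_peak(self):
        t = np.arange(1000) * DT
        period = 100  # frames
        z = 10.0 * np.sin(2 * np.pi * t / (period * DT))
        events = EventTable.from_arrays(
            np.arange(0, 900, period), np.arange(65, 965, period),
            np.arange(period, 900 + period, period),
        )
        assert vertical_excursion(z, events) == pytest.approx(20.0, rel=1e-3)

    def test_constant_height_gives_zero(self):
        z = np.full(500, 950.0)
        events = EventTable.from_arrays([0], [65], [100])
        assert vertical_excursion(z, events) == 0.0

    def test_no_complete_steps_rejected(self):
        z = np.zeros(50)
        events = EventTable.from_arrays([100], [165], [200])
        with pytest.raises(ValueError, match="steps"):
            vertical_excursion(z, events)

    def test_generator_parameter_recovered(self, noise_free_subject):
        cen = pelvic_centroid(noise_free_subject.dynamic)
        exc = vertical_excursion(cen, noise_free_subject.events)
        assert exc == pytest.approx(noise_free_subject.truth_excursion_mm, rel=0.01)
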