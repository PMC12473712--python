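"""Pose-to-IMU transform: closed-form kinematics, filtering, invariances."""

import numpy as np
import pytest

from pose2imu import imugen, quatmath as qm
from pose2imu.imugen import PoseRecording

from conftest import smooth_orientations, smooth_recording

RNG = np.random.default_rng(77)


def constant_rate_z(rate, fs, duration):
    t = np.arange(0, duration, 1.0 / fs)
    return qm.from_axis_angle(np.array([0.0, 0.0, 1.0]), rate * t), t


class TestContinuity:
    def test_already_continuous_untouched(self):
        q = smooth_orientations(RNG, 100)
        np.testing.assert_array_equal(imugen.enforce_continuity(q), q)

    def test_single_flip_healed(self):
        q = np.tile(qm.random_unit_quaternions(1, RNG), (2, 1))
        q[1] *= -1
        healed = imugen.enforce_continuity(q)
        np.testing.assert_array_equal(healed[1], healed[0])

    def test_random_flips_recovered_exactly(self):
        smooth = smooth_orientations(np.random.default_rng(5), 200)
        corrupted = smooth.copy()
        flip_at = np.random.default_rng(6).choice(np.arange(1, 200), 5, replace=False)
        for i in flip_at:
            corrupted[i:] *= -1  # a sign flip persists until the next flip
        np.testing.assert_array_equal(imugen.enforce_continuity(corrupted), smooth)


class TestQuatDerivative:
    def test_constant_sequence_zero(self):
        q = np.tile(qm.IDENTITY, (10, 1))
        np.testing.assert_array_equal(imugen.quat_derivative(q, 0.1), np.zeros((10, 4)))

    def test_two_sample_arithmetic(self):
        q = np.array([[1.0, 0, 0, 0], [0.9, 0.1, 0, 0]])
        d = imugen.quat_derivative(q, 0.1)
        np.testing.assert_allclose(d[0], [-1.0, 1.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_array_equal(d[0], d[1])  # end-padding duplicates

    def test_rejects_short_input(self):
        with pytest.raises(ValueError, match="2 samples"):
            imugen.quat_derivative(np.array([[1.0, 0, 0, 0]]), 0.1)


class TestBodyVelocity:
    def test_stationary_gives_zeros(self):
        rec = PoseRecording(np.zeros((50, 3)), smooth_orientations(RNG, 50), 60.0)
        np.testing.assert_allclose(imugen.body_velocity(rec), 0.0, atol=1e-12)

    def test_constant_world_velocity_rotated_into_body(self):
        fs = 60.0
        t = np.arange(120) / fs
        pos = np.stack([t, np.zeros_like(t), np.zeros_like(t)], axis=1)  # 1 m/s on X
        yaw90 = np.tile([np.sqrt(0.5), 0.0, 0.0, np.sqrt(0.5)], (120, 1))
        v = imugen.body_velocity(PoseRecording(pos, yaw90, fs))
        np.testing.assert_allclose(v, np.tile([0.0, -1.0, 0.0], (120, 1)), atol=1e-9)

    def test_speed_equals_world_speed(self):
        rec = smooth_recording(np.random.default_rng(8))
        v = imugen.body_velocity(rec)
        world = np.diff(rec.positions, axis=0) / rec.dt
        np.testing.assert_allclose(
            np.linalg.norm(v[:-1], axis=1), np.linalg.norm(world, axis=1), atol=1e-10
        )


class TestBodyAcceleration:
    def test_affine_trajectory_zero_interior(self):
        # inputs chosen exactly representable in binary so the double forward
        # difference cancels without rounding: the zero is exact, not approximate
        fs = 64.0
        t = np.arange(100) / fs
        pos = np.outer(t, [0.25, -0.5, 1.0]) + np.array([1.0, 2.0, 3.0])
        a = imugen.body_acceleration(
            PoseRecording(pos, np.tile(qm.IDENTITY, (100, 1)), fs)
        )
        np.testing.assert_array_equal(a[:-2], np.zeros((98, 3)))  # exact

    def test_quadratic_recovers_g(self):
        fs, g = 60.0, 9.81
        t = np.arange(100) / fs
        pos = np.stack([0.5 * g * t**2, 0 * t, 0 * t], axis=1)
        a = imugen.body_acceleration(
            PoseRecording(pos, np.tile(qm.IDENTITY, (100, 1)), fs)
        )
        np.testing.assert_allclose(a[:-2, 0], g, rtol=1e-6)

    def test_centripetal_magnitude(self):
        fs, radius, f_rot = 60.0, 0.5, 1.0
        t = np.arange(0, 3, 1 / fs)
        pos = radius * np.stack(
            [np.cos(2 * np.pi * f_rot * t), np.sin(2 * np.pi * f_rot * t), 0 * t],
            axis=1,
        )
        a = imugen.body_acceleration(
            PoseRecording(pos, np.tile(qm.IDENTITY, (len(t), 1)), fs)
        )
        expected = radius * (2 * np.pi * f_rot) ** 2  # 19.74 m/s^2
        mags = np.linalg.norm(a[: len(t) - 2], axis=1)
        np.testing.assert_allclose(mags, expected, rtol=0.01)

    def test_gravity_flag_adds_body_frame_gravity(self):
        rec = PoseRecording(np.zeros((50, 3)), np.tile(qm.IDENTITY, (50, 1)), 60.0)
        a = imugen.body_acceleration(rec, add_gravity=True)
        np.testing.assert_allclose(a, np.tile(-imugen.GRAVITY, (50, 1)), atol=1e-12)


class TestAngularVelocity:
    def test_constant_orientation_zero(self):
        q = np.tile(qm.random_unit_quaternions(1, RNG)[0], (20, 1))
        np.testing.assert_array_equal(
            imugen.angular_velocity(q, 1 / 60), np.zeros((20, 3))
        )

    def test_constant_rate_about_z(self):
        q, t = constant_rate_z(np.pi, 60.0, 3.0)
        w = imugen.angular_velocity(q, 1 / 60.0)
        mean = w[:-1].mean(axis=0)
        assert abs(mean[2] - np.pi) < 0.02
        assert abs(mean[0]) < 0.02 and abs(mean[1]) < 0.02

    def test_matrix_equals_conjugate_product(self):
        for seed in range(20):
            q = smooth_orientations(np.random.default_rng(seed), 150)
            wm = imugen.angular_velocity(q, 1 / 60.0, method="matrix")
            wc = imugen.angular_velocity(q, 1 / 60.0, method="conjugate")
            np.testing.assert_allclose(wm, wc, atol=1e-12)

    def test_error_shrinks_with_sample_rate(self):
        # first-order scheme: halving dt should at least halve the error
        errs = []
        for fs in (30.0, 60.0, 120.0):
            q, _ = constant_rate_z(np.pi, fs, 2.0)
            w = imugen.angular_velocity(q, 1 / fs)
            errs.append(np.abs(w[:-1, 2] - np.pi).max())
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[1] > 1.8 and errs[1] / errs[2] > 1.8

    def test_rejects_non_unit(self):
        q = np.tile([2.0, 0, 0, 0], (5, 1))
        with pytest.raises(ValueError, match="unit"):
            imugen.angular_velocity(q, 0.01)


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full((600, 3), 5.0)
        np.testing.assert_allclose(imugen.lowpass(x, 3.0, 60.0), 5.0, atol=1e-9)

    def test_half_power_at_cutoff(self):
        fs, n = 60.0, 600  # 10 s
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 3.0 * t)[:, None]
        y = imugen.lowpass(x, 3.0, fs)
        mid = slice(n // 4, 3 * n // 4)
        ratio = np.abs(y[mid]).max() / np.abs(x[mid]).max()
        assert abs(ratio - 0.5) < 0.025  # two forward/backward passes of -3 dB

    def test_stop_band(self):
        fs, n = 60.0, 600
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 20.0 * t)[:, None]
        y = imugen.lowpass(x, 3.0, fs)
        assert np.abs(y[n // 4 : 3 * n // 4]).max() < 0.01

    def test_rejects_cutoff_at_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            imugen.lowpass(np.zeros((100, 1)), 30.0, 60.0)


class TestTransformRecording:
    def test_stationary_recording_all_zero(self):
        rec = PoseRecording(np.zeros((64, 3)), np.tile(qm.IDENTITY, (64, 1)), 45.0)
        kin = imugen.transform_recording(rec)
        for channel in (kin.velocity, kin.acceleration, kin.angular_velocity):
            np.testing.assert_allclose(channel, 0.0, atol=1e-12)

    def test_filtering_removes_variance(self):
        rec = smooth_recording(np.random.default_rng(12))
        raw = imugen.transform_recording(rec, cutoff=None)
        filt = imugen.transform_recording(rec, cutoff=3.0)
        assert np.all(filt.acceleration.var(axis=0) < raw.acceleration.var(axis=0))

    def test_world_frame_invariance(self):
        # pre-rotating the whole world must not change body-frame signals
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rec = smooth_recording(rng)
            r = qm.random_unit_quaternions(1, rng)[0]
            rotated = PoseRecording(
                qm.rotate_body_to_world(r, rec.positions),
                qm.hamilton_product(r, rec.orientations),
                rec.sample_rate,
            )
            kin0 = imugen.transform_recording(rec, cutoff=3.0)
            kin1 = imugen.transform_recording(rotated, cutoff=3.0)
            np.testing.assert_allclose(kin1.velocity, kin0.velocity, atol=1e-9)
            np.testing.assert_allclose(kin1.acceleration, kin0.acceleration, atol=1e-9)
            np.testing.assert_allclose(
                kin1.angular_velocity, kin0.angular_velocity, atol=1e-9
            )

    def test_rejects_degenerate_recordings(self):
        with pytest.raises(ValueError, match="3 samples"):
            PoseRecording(np.zeros((2, 3)), np.tile(qm.IDENTITY, (2, 1)), 60.0)
        with pytest.raises(ValueError, match="unit"):
            PoseRecording(np.zeros((5, 3)), np.full((5, 4), 0.9), 60.0)
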