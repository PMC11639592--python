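"""Alignment, joint angles, metrics and repetition counting."""

import numpy as np
import pytest

from spineimu.errors import InsufficientDataError, InvalidArgumentError
from spineimu.fusion import OrientationTrack
from spineimu.kinematics import (JointAngleTrack, calibrate_alignment,
                                 compare_tracks, count_repetitions,
                                 extract_angle, joint_track, segment_orientation)
from spineimu.quatcore import (qcanonical, qconj, qmul, qnormalize,
                               quat_angle_deg, quat_from_axis_angle,
                               quat_to_matrix)

IDENT = np.array([1.0, 0.0, 0.0, 0.0])


def const_track(q, n=400, rate=100.0):
    return OrientationTrack(np.tile(q, (n, 1)), rate)


class TestCalibration:
    def test_identity_tracks_give_identity_alignment(self):
        a = calibrate_alignment(const_track(IDENT), const_track(IDENT))
        np.testing.assert_allclose(a.q_proximal, IDENT, atol=1e-12)
        np.testing.assert_allclose(a.q_distal, IDENT, atol=1e-12)

    def test_constant_track_gives_conjugate(self, rng):
        q0 = qcanonical(qnormalize(rng.standard_normal(4)))
        a = calibrate_alignment(const_track(q0), const_track(q0))
        np.testing.assert_allclose(a.q_distal, qcanonical(qconj(q0)), atol=1e-12)
        np.testing.assert_allclose(qcanonical(qmul(q0, a.q_distal)), IDENT, atol=1e-12)

    @pytest.mark.filterwarnings("ignore:motion of")
    def test_noisy_track_alignment_within_half_degree(self, rng):
        # per-frame orientation noise looks like fast motion to the RMS check
        q0 = qcanonical(qnormalize(rng.standard_normal(4)))
        errs = []
        for _ in range(100):
            axes = rng.standard_normal((300, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            ang = rng.normal(0, np.radians(1.0), 300)
            noise = np.concatenate([np.cos(ang / 2)[:, None],
                                    np.sin(ang / 2)[:, None] * axes], axis=1)
            track = OrientationTrack(qmul(q0, noise), 100.0)
            a = calibrate_alignment(track, track)
            errs.append(float(quat_angle_deg(a.q_distal, qconj(q0))))
        assert np.mean(errs) < 0.5

    def test_short_track_errors(self):
        with pytest.raises(InsufficientDataError):
            calibrate_alignment(const_track(IDENT, n=100), const_track(IDENT, n=100),
                                static_window_s=3.0)

    def test_zero_point_property(self, rng):
        """Both segment orientations are identity at calibration."""
        qp = qnormalize(rng.standard_normal(4))
        qd = qnormalize(rng.standard_normal(4))
        tp, td = const_track(qp), const_track(qd)
        a = calibrate_alignment(tp, td)
        seg_p = segment_orientation(tp, a, "proximal")
        seg_d = segment_orientation(td, a, "distal")
        assert np.max(quat_angle_deg(seg_p.quats)) < 1e-6
        assert np.max(quat_angle_deg(seg_d.quats)) < 1e-6
        joint = joint_track(seg_p, seg_d)
        assert np.max(quat_angle_deg(joint.quats)) < 1e-6


class TestJoint:
    def test_equal_tracks_give_identity_joint(self, rng):
        q = qnormalize(rng.standard_normal((50, 4)))
        t = OrientationTrack(q, 100.0)
        assert np.max(quat_angle_deg(joint_track(t, t).quats)) < 1e-9

    def test_identity_proximal_passes_distal_through(self, rng):
        qd = qcanonical(qnormalize(rng.standard_normal((50, 4))))
        tp = OrientationTrack(np.tile(IDENT, (50, 1)), 100.0)
        td = OrientationTrack(qd, 100.0)
        np.testing.assert_allclose(joint_track(tp, td).quats, qd, atol=1e-12)

    def test_against_relative_rotation_matrix_oracle(self, rng):
        qp = qnormalize(rng.standard_normal((50, 4)))
        qd = qnormalize(rng.standard_normal((50, 4)))
        joint = joint_track(OrientationTrack(qp, 100.0), OrientationTrack(qd, 100.0))
        R_joint = quat_to_matrix(joint.quats)
        R_oracle = np.einsum("nji,njk->nik", quat_to_matrix(qp), quat_to_matrix(qd))
        np.testing.assert_allclose(R_joint, R_oracle, atol=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            joint_track(const_track(IDENT, 10), const_track(IDENT, 11))


class TestExtractAngle:
    def test_identity_track_is_zero(self):
        t = extract_angle(const_track(IDENT, 50), "flexion")
        np.testing.assert_allclose(t.angle, 0.0, atol=1e-12)

    def test_pure_z_rotation_is_flexion(self):
        q = quat_from_axis_angle([0, 0, 1], np.radians(25.0))
        t = extract_angle(const_track(q, 10), "flexion")
        np.testing.assert_allclose(t.angle, 25.0, atol=1e-9)

    def test_orthogonal_channel_is_zero(self):
        q = quat_from_axis_angle([0, 0, 1], np.radians(25.0))
        t = extract_angle(const_track(q, 10), "abduction")
        np.testing.assert_allclose(t.angle, 0.0, atol=1e-9)

    def test_unwrap_no_360_jumps(self):
        # yaw sweep crossing +/-180: unwrapped output must stay continuous
        angles = np.radians(np.linspace(0, 350, 500))
        quats = quat_from_axis_angle([0, 1, 0], angles)
        t = extract_angle(OrientationTrack(quats, 100.0), "rotation")
        assert np.max(np.abs(np.diff(t.angle))) < 5.0
        np.testing.assert_allclose(t.angle[-1], 350.0, atol=1e-6)

    def test_gimbal_frames_flagged_not_raised(self):
        q = quat_from_axis_angle([1, 0, 0], np.radians(-90.0))
        t = extract_angle(const_track(q, 5), "abduction")
        assert len(t.gimbal_frames) == 5

    def test_unknown_channel(self):
        with pytest.raises(InvalidArgumentError):
            extract_angle(const_track(IDENT, 5), "twist")


def raised_cosine(n_cycles=5, amp=40.0, period_samples=200):
    t = np.arange(n_cycles * period_samples)
    return amp / 2 * (1 - np.cos(2 * np.pi * t / period_samples))


class TestMetrics:
    def test_identical_tracks(self):
        x = raised_cosine()
        m = compare_tracks(x, x)
        assert m.mae == 0.0 and m.peak_error == 0.0 and m.mean_velocity_error == 0.0

    def test_constant_offset(self):
        x = raised_cosine()
        m = compare_tracks(x + 2.0, x)
        np.testing.assert_allclose(m.mae, 2.0, atol=1e-12)
        np.testing.assert_allclose(m.mean_velocity_error, 0.0, atol=1e-9)

    def test_scaled_sinusoid_peak_error(self):
        ref = raised_cosine(amp=40.0)
        m = compare_tracks(1.1 * ref, ref)
        np.testing.assert_allclose(m.peak_error, 4.0, atol=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            compare_tracks(np.zeros(5), np.zeros(6))


class TestRepetitions:
    def test_constant_track_zero(self):
        assert count_repetitions(np.full(100, 7.0)) == 0

    def test_five_cycles(self):
        assert count_repetitions(raised_cosine(5)) == 5

    def test_noisy_cycles_robust_across_seeds(self):
        x = raised_cosine(5, amp=40.0)
        master = np.random.default_rng(42)
        counts = [count_repetitions(x + master.normal(0, 1.0, x.shape))
                  for _ in range(100)]
        assert counts == [5] * 100

    def test_track_object_accepted(self):
        x = raised_cosine(3)
        track = JointAngleTrack(t=np.arange(len(x)) / 100.0, angle=x,
                                alpha=x, beta=x, gamma=x, sample_rate=100.0)
        assert count_repetitions(track) == 3
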