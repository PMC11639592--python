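"""Synthetic rigid-body IMU trials with known ground-truth kinematics.

Two rigid segments share a joint.  The proximal segment holds a static
orientation; the distal segment rotates about the anatomical axis of the
exercise's Euler channel (flexion -> global z, rotation -> y, abduction -> x)
following a raised-cosine repetition profile

    theta(t) = A/2 * (1 - cos(2*pi*t / T))     per repetition,

preceded by a 3-s static lead-in that stands in for the calibration pose.
The profile is smooth (continuous velocity and acceleration), so filter-lag
effects are not confounded by kinks.

Sensor models: gyro = body rate + constant bias + white noise; accelerometer
= body-frame gravity + lever-arm linear acceleration (rigid-body
``alpha x r + omega x (omega x r)`` with a 0.1 m arm) + white noise;
magnetometer = body-frame projection of a fixed field + white noise.  Frames
are dropped i.i.d. (emulating Bluetooth loss) and the survivors keep their
original package numbers, leaving gaps for the repair stage.

A separate generator produces the placement-identification corpus: for each
subject x exercise x IMU site, a 10-s stream whose site signature is a
site-specific static orientation (distinct gravity axis in the sensor frame)
plus site-specific oscillation amplitude/frequency, with per-subject jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .exercise_registry import EXERCISES, ExerciseSpec, LOCATIONS, get_spec, list_exercises
from .features import LabeledStream
from .fusion import DEFAULT_M_REF
from .imu_stream import ImuStream
from .kinematics import JointAngleTrack
from .quatcore import (qconj, qmul, qnormalize, qrotate, quat_from_axis_angle,
                       quat_to_matrix)

__all__ = [
    "NoiseModel",
    "TrialScenario",
    "CHANNEL_AXES",
    "angle_profile",
    "synthesize_trial",
    "synthesize_bias_capture",
    "synthesize_location_dataset",
]

#: Rotation axis (global frame) realizing each Euler channel.
CHANNEL_AXES = {
    "flexion": np.array([0.0, 0.0, 1.0]),    # gamma, z-roll
    "rotation": np.array([0.0, 1.0, 0.0]),   # alpha, y-yaw
    "abduction": np.array([1.0, 0.0, 0.0]),  # beta, x-pitch
}

GRAVITY = np.array([0.0, 0.0, 9.81])
#: Magnetic field vector, uT: mid-latitude direction at a 50 uT magnitude.
MAG_FIELD = 50.0 * np.asarray(DEFAULT_M_REF)

#: Default range of motion per channel, degrees (placeholder magnitudes of a
#: plausible active range; real per-exercise ROMs are subject-specific).
DEFAULT_AMPLITUDE_DEG = {"flexion": 40.0, "rotation": 60.0, "abduction": 40.0}


@dataclass(frozen=True)
class NoiseModel:
    """Consumer-grade IMU imperfections.

    gyro_sigma : white-noise std per sample, rad/s
    gyro_bias : constant per-axis bias, rad/s
    acc_sigma : accelerometer white-noise std, m/s^2
    mag_sigma : magnetometer white-noise std, uT
    drop_prob : i.i.d. per-frame Bluetooth loss probability
    """

    gyro_sigma: float = 0.005
    gyro_bias: tuple[float, float, float] = (0.01, 0.01, 0.01)
    acc_sigma: float = 0.05
    mag_sigma: float = 0.5
    drop_prob: float = 0.0

    def __post_init__(self) -> None:
        if min(self.gyro_sigma, self.acc_sigma, self.mag_sigma) < 0:
            raise InvalidArgumentError("noise sigmas must be non-negative")
        if not 0.0 <= self.drop_prob < 0.1:
            raise InvalidArgumentError("drop_prob must be in [0, 0.1)")

    @classmethod
    def noise_free(cls) -> "NoiseModel":
        return cls(gyro_sigma=0.0, gyro_bias=(0.0, 0.0, 0.0), acc_sigma=0.0,
                   mag_sigma=0.0, drop_prob=0.0)


# Fixed non-trivial sensor mountings so the calibration step actually works
# for its living: proximal IMU tilted, distal IMU rotated against its segment.
_Q_PROX_STATIC = qnormalize(qmul(quat_from_axis_angle([1, 0, 0], np.radians(15.0)),
                                 quat_from_axis_angle([0, 1, 0], np.radians(10.0))))
_Q_DIST_MOUNT = qnormalize(qmul(quat_from_axis_angle([0, 0, 1], np.radians(25.0)),
                                quat_from_axis_angle([1, 0, 0], np.radians(-12.0))))


@dataclass(frozen=True)
class TrialScenario:
    """One synthetic exercise trial: five repetitions after a 3-s static lead."""

    exercise: str | ExerciseSpec = "windmill single leg"
    amplitude_deg: float | None = None  # default per channel
    n_reps: int = 5
    rep_period_s: float = 3.0
    static_lead_s: float = 3.0
    rate: float = 100.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    lever_arm_m: float = 0.1

    def __post_init__(self) -> None:
        if self.rep_period_s <= 0 or self.n_reps < 1 or self.rate <= 0:
            raise InvalidArgumentError("invalid scenario timing")
        if self.amplitude_deg is not None and self.amplitude_deg <= 0:
            raise InvalidArgumentError("amplitude must be positive")

    @property
    def spec(self) -> ExerciseSpec:
        return self.exercise if isinstance(self.exercise, ExerciseSpec) else get_spec(self.exercise)

    @property
    def amplitude(self) -> float:
        if self.amplitude_deg is not None:
            return self.amplitude_deg
        return DEFAULT_AMPLITUDE_DEG[self.spec.channel]

    @property
    def n_frames(self) -> int:
        return int(round(self.rate * (self.static_lead_s + self.n_reps * self.rep_period_s)))


def _profile_deg(s: TrialScenario):
    """theta, dtheta/dt, d2theta/dt2 in degrees (and /s, /s^2)."""
    t = np.arange(s.n_frames) / s.rate
    tau = t - s.static_lead_s
    A, T = s.amplitude, s.rep_period_s
    w = 2.0 * np.pi / T
    active = tau >= 0.0
    theta = np.where(active, 0.5 * A * (1.0 - np.cos(w * tau)), 0.0)
    dtheta = np.where(active, 0.5 * A * w * np.sin(w * tau), 0.0)
    ddtheta = np.where(active, 0.5 * A * w * w * np.cos(w * tau), 0.0)
    return t, theta, dtheta, ddtheta


def angle_profile(s: TrialScenario) -> JointAngleTrack:
    """Ground-truth joint angle track for a scenario (no sensors involved)."""
    t, theta, _, _ = _profile_deg(s)
    zeros = np.zeros_like(theta)
    channel = s.spec.channel
    euler = {"alpha": zeros.copy(), "beta": zeros.copy(), "gamma": zeros.copy()}
    from .kinematics import CHANNEL_TO_EULER

    euler[CHANNEL_TO_EULER[channel]] = theta
    return JointAngleTrack(t=t, angle=theta, alpha=euler["alpha"],
                           beta=euler["beta"], gamma=euler["gamma"],
                           sample_rate=s.rate, channel=channel)


def _sensor_outputs(quats, omega_body, lin_acc_global, noise, rng):
    """acc/gyr/mag arrays of a sensor following orientation track ``quats``."""
    n = len(quats)
    q_inv = qconj(quats)
    acc = qrotate(q_inv, GRAVITY + lin_acc_global)
    mag = qrotate(q_inv, MAG_FIELD[None, :].repeat(n, axis=0))
    gyr = omega_body + np.asarray(noise.gyro_bias)
    if noise.acc_sigma > 0:
        acc = acc + rng.normal(0.0, noise.acc_sigma, (n, 3))
    if noise.gyro_sigma > 0:
        gyr = gyr + rng.normal(0.0, noise.gyro_sigma, (n, 3))
    if noise.mag_sigma > 0:
        mag = mag + rng.normal(0.0, noise.mag_sigma, (n, 3))
    return acc, gyr, mag


def _drop_frames(n: int, drop_prob: float, rng) -> np.ndarray:
    """Surviving frame indices under i.i.d. loss; endpoints always survive."""
    keep = rng.random(n) >= drop_prob
    keep[0] = keep[-1] = True
    return np.flatnonzero(keep)


def synthesize_trial(s: TrialScenario) -> tuple[ImuStream, ImuStream, JointAngleTrack]:
    """Simulate the two IMU streams and ground truth of one exercise trial.

    Running the full estimation pipeline on the noise-free output reproduces
    the truth (inverse consistency).  Deterministic given the scenario seed.
    """
    rng = np.random.default_rng(s.seed)
    t, theta, dtheta, ddtheta = _profile_deg(s)
    axis = CHANNEL_AXES[s.spec.channel]
    th = np.radians(theta)
    dth = np.radians(dtheta)
    ddth = np.radians(ddtheta)
    n = s.n_frames

    q_rot = quat_from_axis_angle(axis, th)            # (n, 4) global-axis rotation
    q_prox = np.broadcast_to(_Q_PROX_STATIC, (n, 4)).copy()
    q_dist = qmul(q_rot, qmul(_Q_PROX_STATIC[None, :], _Q_DIST_MOUNT[None, :]))

    # distal body rate: global rate dtheta * axis seen in the sensor frame
    omega_global = dth[:, None] * axis
    omega_dist = qrotate(qconj(q_dist), omega_global)
    # lever arm: sensor sits lever_arm_m from the joint, perpendicular to axis
    perp = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    r0 = s.lever_arm_m * np.cross(axis, perp)
    r = qrotate(q_rot, r0[None, :].repeat(n, axis=0))
    lin_acc = (ddth[:, None] * np.cross(axis, r)
               + dth[:, None] ** 2 * np.cross(axis, np.cross(axis, r)))

    acc_p, gyr_p, mag_p = _sensor_outputs(q_prox, np.zeros((n, 3)), np.zeros((n, 3)),
                                          s.noise, rng)
    acc_d, gyr_d, mag_d = _sensor_outputs(q_dist, omega_dist, lin_acc, s.noise, rng)

    keep_p = _drop_frames(n, s.noise.drop_prob, rng)
    keep_d = _drop_frames(n, s.noise.drop_prob, rng)
    prox = ImuStream("proximal", keep_p, acc_p[keep_p], gyr_p[keep_p],
                     mag_p[keep_p], s.rate)
    dist = ImuStream("distal", keep_d, acc_d[keep_d], gyr_d[keep_d],
                     mag_d[keep_d], s.rate)
    return prox, dist, angle_profile(s)


def synthesize_bias_capture(
    noise: NoiseModel, seed: int, duration_s: float = 10.0, rate: float = 100.0,
    sensor_id: str = "table",
) -> ImuStream:
    """Static table-rest capture for gyro-bias calibration (sensor flat)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    quats = np.broadcast_to(np.array([1.0, 0.0, 0.0, 0.0]), (n, 4)).copy()
    acc, gyr, mag = _sensor_outputs(quats, np.zeros((n, 3)), np.zeros((n, 3)),
                                    noise, rng)
    return ImuStream(sensor_id, np.arange(n), acc, gyr, mag, rate)


# --- placement-identification corpus ---------------------------------------

# Site signatures: static orientation (gravity axis in the sensor frame),
# oscillation axis (body frame), amplitude (deg) and frequency (Hz).
_SITE_SIGNATURES = {
    "head": (quat_from_axis_angle([1, 0, 0], 0.0), [0, 0, 1], 10.0, 0.8),
    "thorax": (quat_from_axis_angle([1, 0, 0], np.pi / 2), [1, 0, 0], 20.0, 1.2),
    "pelvis": (quat_from_axis_angle([0, 1, 0], np.pi / 2), [0, 1, 0], 15.0, 0.6),
    "upper_arm": (quat_from_axis_angle([1, 0, 0], np.pi), [0, 0, 1], 30.0, 1.5),
    "thigh": (quat_from_axis_angle([0, 1, 0], -np.pi / 2), [1, 0, 0], 25.0, 1.0),
}


def synthesize_location_dataset(
    n_subjects: int = 12,
    seed: int = 0,
    duration_s: float = 10.0,
    rate: float = 100.0,
    noise: NoiseModel | None = None,
    static_lead_s: float = 3.0,
    locations: tuple[str, ...] = LOCATIONS,
    exercises: list[str] | None = None,
) -> list[LabeledStream]:
    """Labeled streams for every subject x exercise x IMU site.

    Each stream starts with a static lead (the calibration pose) and then
    oscillates about a site-specific body axis; the gravity direction in the
    sensor frame, amplitude and frequency identify the site.  Subjects add
    consistent jitter (orientation up to ~5 deg/axis, amplitude/frequency
    ~10-15%), and exercises modulate frequency and phase, so windows of one
    subject resemble each other more than those of another subject — the
    structure subject-wise splitting must survive.  Deterministic given seed.
    """
    if n_subjects < 4:
        raise InvalidArgumentError("need at least 4 subjects for subject-wise splits")
    noise = noise or NoiseModel()
    exercises = exercises if exercises is not None else list_exercises()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    out: list[LabeledStream] = []
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        for location in locations:
            q_base, axis, amp_deg, freq = _SITE_SIGNATURES[location]
            axis = np.asarray(axis, dtype=float)
            # subject-consistent jitter
            tilt = rng.normal(0.0, np.radians(5.0), 3)
            q_jit = q_base
            for k, ang in enumerate(tilt):
                e = np.zeros(3)
                e[k] = 1.0
                q_jit = qmul(q_jit, quat_from_axis_angle(e, ang))
            amp_s = amp_deg * (1.0 + 0.15 * rng.standard_normal())
            freq_s = freq * (1.0 + 0.10 * rng.standard_normal())
            bias = rng.normal(0.0, 0.01, 3)
            for ei, exercise in enumerate(exercises):
                f = freq_s * (0.85 + 0.3 * ei / max(len(exercises) - 1, 1))
                tau = np.maximum(t - static_lead_s, 0.0)
                th = np.radians(amp_s) * np.sin(2 * np.pi * f * tau) * (tau > 0)
                dth = (np.radians(amp_s) * 2 * np.pi * f
                       * np.cos(2 * np.pi * f * tau) * (tau > 0))
                # oscillation about a body-fixed axis: omega is constant in body frame
                quats = qmul(q_jit[None, :], quat_from_axis_angle(axis, th))
                omega_body = dth[:, None] * axis
                stream_noise = NoiseModel(
                    gyro_sigma=noise.gyro_sigma, gyro_bias=tuple(bias),
                    acc_sigma=noise.acc_sigma, mag_sigma=noise.mag_sigma,
                    drop_prob=0.0,
                )
                acc, gyr, mag = _sensor_outputs(quats, omega_body,
                                                np.zeros((n, 3)), stream_noise, rng)
                stream = ImuStream(f"{subject}-{location}", np.arange(n),
                                   acc, gyr, mag, rate)
                out.append(LabeledStream(stream=stream, location=location,
                                         subject=subject, exercise=exercise))
    return out
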