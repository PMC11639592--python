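"""Joint-angle estimation from two orientation tracks.

The four-step procedure:

1. per-IMU orientation from sensor fusion (module :mod:`spineimu.fusion`);
2. static IMU-to-segment alignment from the 3-s initial pose: each sensor's
   alignment is the conjugate of its mean orientation over the window, so
   both segment orientations — and hence the joint quaternion — are identity
   at calibration, making the initial pose the zero-point of every angle;
3. joint quaternion = (proximal segment)^* (x) (distal segment);
4. ZXY Euler extraction of the exercise channel (flexion = gamma,
   rotation = alpha, abduction = beta).

Also provides the evaluation metrics (MAE, signed per-repetition peak error,
mean velocity error) and a hysteresis repetition counter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError
from .fusion import FilterParams, OrientationTrack, fuse
from .imu_stream import (GyroBias, ImuStream, align_streams, estimate_gyro_bias,
                         repair_stream, subtract_bias)
from .quatcore import (euler_zxy_track, qcanonical, qconj, qmean, qmul,
                       quat_angle_deg, quat_to_matrix)

__all__ = [
    "SegmentAlignment",
    "JointAngleTrack",
    "AngleMetrics",
    "CHANNEL_TO_EULER",
    "calibrate_alignment",
    "segment_orientation",
    "joint_track",
    "extract_angle",
    "compare_tracks",
    "count_repetitions",
    "estimate_joint_angles",
    "AngleEstimationResult",
]

#: Exercise channel -> ZXY Euler component.
CHANNEL_TO_EULER = {"flexion": "gamma", "rotation": "alpha", "abduction": "beta"}


@dataclass(frozen=True)
class SegmentAlignment:
    """Constant IMU-to-segment quaternions for the two sensors of a trial."""

    q_proximal: np.ndarray
    q_distal: np.ndarray


@dataclass
class JointAngleTrack:
    """Per-frame joint Euler angles with the exercise channel selected.

    ``angle`` is the selected channel in degrees; ``alpha/beta/gamma`` keep
    the full decomposition.  ``gimbal_frames`` lists frame indices where the
    extraction sat inside the gimbal-lock band.
    """

    t: np.ndarray
    angle: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    sample_rate: float
    channel: str = "flexion"
    gimbal_frames: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.angle)


@dataclass(frozen=True)
class AngleMetrics:
    """Agreement metrics between an estimated and a reference angle track."""

    mae: float                  # deg
    peak_error: float           # deg, signed, averaged over repetitions
    mean_velocity_error: float  # deg/s

    def as_dict(self) -> dict:
        return {"mae_deg": self.mae, "peak_error_deg": self.peak_error,
                "mean_velocity_error_deg_s": self.mean_velocity_error}


def calibrate_alignment(
    track_prox: OrientationTrack,
    track_dist: OrientationTrack,
    static_window_s: float = 3.0,
) -> SegmentAlignment:
    """IMU-to-segment alignment from the static initial pose.

    The alignment of each sensor is the conjugate of its mean orientation
    over the window (chordal mean via the dominant eigenvector of the
    quaternion outer-product sum, which is sign-robust).  By construction the
    segment orientations are identity at calibration, so the initial pose is
    the zero-point of the joint angles.
    """
    aligns = []
    for track in (track_prox, track_dist):
        n = int(round(static_window_s * track.sample_rate))
        if len(track) < n or n < 1:
            raise InsufficientDataError(
                f"track has {len(track)} frames, need {n} for a "
                f"{static_window_s:g} s static window"
            )
        window = track.quats[:n]
        if n > 1:
            step_deg = quat_angle_deg(window[:-1], window[1:])
            rms_speed = float(np.sqrt(np.mean(step_deg**2))) * track.sample_rate
            if rms_speed > 2.0:
                warnings.warn(
                    f"motion of {rms_speed:.1f} deg/s during the static "
                    "calibration window; alignment may be biased", stacklevel=2,
                )
        aligns.append(qcanonical(qconj(qmean(window))))
    return SegmentAlignment(q_proximal=aligns[0], q_distal=aligns[1])


def segment_orientation(
    track: OrientationTrack, a: SegmentAlignment, sensor: str
) -> OrientationTrack:
    """Segment orientation track: per-frame product q_IMU (x) q_IMU->Segment."""
    if sensor == "proximal":
        q_align = a.q_proximal
    elif sensor == "distal":
        q_align = a.q_distal
    else:
        raise InvalidArgumentError("sensor must be 'proximal' or 'distal'")
    quats = qmul(track.quats, q_align[None, :])
    return OrientationTrack(qcanonical(quats), track.sample_rate)


def joint_track(prox: OrientationTrack, dist: OrientationTrack) -> OrientationTrack:
    """Joint quaternion track: distal segment expressed in the proximal frame."""
    if len(prox) != len(dist):
        raise InvalidArgumentError(
            f"track lengths differ: {len(prox)} vs {len(dist)}"
        )
    quats = qmul(qconj(prox.quats), dist.quats)
    return OrientationTrack(qcanonical(quats), prox.sample_rate)


def extract_angle(joint: OrientationTrack, channel: str) -> JointAngleTrack:
    """ZXY Euler angles of a joint track with one channel selected.

    alpha and gamma are unwrapped (no +/-360 deg jumps between adjacent
    frames); beta is bounded in [-90, 90] by construction.  Frames inside the
    gimbal-lock band are flagged, not raised: a transient crossing should not
    abort a whole trial.
    """
    if channel not in CHANNEL_TO_EULER:
        raise InvalidArgumentError(
            f"channel must be one of {sorted(CHANNEL_TO_EULER)}, got {channel!r}"
        )
    R = quat_to_matrix(joint.quats)
    alpha, beta, gamma, gimbal = euler_zxy_track(R)
    alpha = np.degrees(np.unwrap(np.radians(alpha)))
    gamma = np.degrees(np.unwrap(np.radians(gamma)))
    angle = {"alpha": alpha, "beta": beta, "gamma": gamma}[CHANNEL_TO_EULER[channel]]
    return JointAngleTrack(
        t=joint.t,
        angle=angle,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        sample_rate=joint.sample_rate,
        channel=channel,
        gimbal_frames=tuple(int(i) for i in np.flatnonzero(gimbal)),
    )


def _angle_array(track) -> np.ndarray:
    return np.asarray(track.angle if hasattr(track, "angle") else track, dtype=float)


def _rep_segments(x: np.ndarray, threshold_fraction: float, hysteresis: float = 0.1):
    """Excursion segments above threshold_fraction of the track's range.

    A repetition starts when the signal rises above
    ``min + threshold_fraction * range`` having previously been below the
    lower (hysteresis) threshold, and ends when it falls back below the lower
    threshold.  Returns a list of (start, end) index pairs.
    """
    lo_v, hi_v = float(np.min(x)), float(np.max(x))
    rng = hi_v - lo_v
    if rng <= 1e-12:
        return []
    high = lo_v + threshold_fraction * rng
    low = lo_v + max(threshold_fraction - hysteresis, threshold_fraction * 0.5) * rng
    segments = []
    armed = x[0] < high
    start = None
    for i in range(len(x)):
        if start is None:
            if armed and x[i] >= high:
                start = i
            elif x[i] < low:
                armed = True
        else:
            if x[i] < low:
                segments.append((start, i))
                start = None
                armed = True
    if start is not None:
        segments.append((start, len(x)))
    return segments


def count_repetitions(track, threshold_fraction: float = 0.5) -> int:
    """Count excursions above a fraction of the track's range, with hysteresis.

    A flat track has zero repetitions.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise InvalidArgumentError("threshold_fraction must be in (0, 1)")
    x = _angle_array(track)
    if x.size == 0:
        raise InvalidArgumentError("empty track")
    return len(_rep_segments(x, threshold_fraction))


def compare_tracks(est, ref) -> AngleMetrics:
    """MAE, signed per-repetition peak error, and mean velocity error.

    * ``mae``: mean absolute difference, degrees.
    * ``peak_error``: repetitions are segmented on the reference track; per
      repetition the difference (est peak - ref peak) is taken signed and
      averaged, so systematic over/undershoot keeps its sign (zero when the
      reference has no repetitions).
    * ``mean_velocity_error``: mean absolute difference of the central-
      difference angular velocities, deg/s.
    """
    e = _angle_array(est)
    r = _angle_array(ref)
    if e.shape != r.shape:
        raise InvalidArgumentError(f"track lengths differ: {e.shape} vs {r.shape}")
    rate = getattr(est, "sample_rate", None) or getattr(ref, "sample_rate", None) or 1.0
    mae = float(np.mean(np.abs(e - r)))
    if len(e) >= 2:
        dt = 1.0 / rate
        vel_err = float(np.mean(np.abs(np.gradient(e, dt) - np.gradient(r, dt))))
    else:
        vel_err = 0.0
    segs = _rep_segments(r, 0.5)
    if segs:
        peaks = [float(np.max(e[a:b]) - np.max(r[a:b])) for a, b in segs]
        peak_error = float(np.mean(peaks))
    else:
        peak_error = 0.0
    return AngleMetrics(mae=mae, peak_error=peak_error, mean_velocity_error=vel_err)


@dataclass
class AngleEstimationResult:
    """Output of the end-to-end pipeline, with repair/calibration diagnostics."""

    track: JointAngleTrack
    alignment: SegmentAlignment
    n_interpolated: int
    gyro_bias_proximal: GyroBias
    gyro_bias_distal: GyroBias


def estimate_joint_angles(
    prox: ImuStream,
    dist: ImuStream,
    channel: str,
    params: FilterParams | None = None,
    static_window_s: float = 3.0,
    bias_capture_prox: ImuStream | None = None,
    bias_capture_dist: ImuStream | None = None,
    bias_window_s: float = 10.0,
) -> AngleEstimationResult:
    """Full pipeline: repair -> bias -> fuse -> calibrate -> joint -> angle.

    Gyro bias comes from the table-rest captures when provided; otherwise it
    is estimated from the trial's own static lead-in (``static_window_s``).
    """
    prox, n1 = repair_stream(prox)
    dist, n2 = repair_stream(dist)
    prox, dist = align_streams(prox, dist)
    if bias_capture_prox is not None:
        bias_p = estimate_gyro_bias(bias_capture_prox, bias_window_s)
    else:
        bias_p = estimate_gyro_bias(prox, static_window_s)
    if bias_capture_dist is not None:
        bias_d = estimate_gyro_bias(bias_capture_dist, bias_window_s)
    else:
        bias_d = estimate_gyro_bias(dist, static_window_s)
    params = params or FilterParams()
    track_p = fuse(subtract_bias(prox, bias_p), params)
    track_d = fuse(subtract_bias(dist, bias_d), params)
    alignment = calibrate_alignment(track_p, track_d, static_window_s)
    seg_p = segment_orientation(track_p, alignment, "proximal")
    seg_d = segment_orientation(track_d, alignment, "distal")
    joint = joint_track(seg_p, seg_d)
    track = extract_angle(joint, channel)
    return AngleEstimationResult(
        track=track,
        alignment=alignment,
        n_interpolated=n1 + n2,
        gyro_bias_proximal=bias_p,
        gyro_bias_distal=bias_d,
    )
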