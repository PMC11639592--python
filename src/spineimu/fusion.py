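"""Attitude estimation: direct complementary filter (nonlinear observer on SO(3)).

Each IMU's orientation relative to the global frame is estimated per frame by
fusing gyroscope integration with accelerometer (gravity direction) and
magnetometer (heading) corrections.  The observer drives the innovation

    e = sum over references of  v_measured x v_predicted   (body frame)

to zero through a corrected angular rate ``omega + kp * e + ki * integral(e)``,
then propagates the quaternion with a first-order integrator at the sample
rate and renormalizes.  The proportional term pulls the tilt/heading toward
the vector observations; the integral term absorbs residual constant gyro
bias that static calibration missed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .imu_stream import ImuStream
from .quatcore import (identity_quat, matrix_to_quat, qcanonical, qconj, qmul,
                       qnormalize, qrotate)

__all__ = ["FilterParams", "OrientationTrack", "fuse", "initial_orientation"]

logger = logging.getLogger(__name__)

#: Default reference magnetic field direction (unit): horizontal north
#: component plus a mid-latitude downward dip of ~50 degrees (global z is up).
DEFAULT_M_REF = (0.6428, 0.0, -0.7660)


@dataclass
class FilterParams:
    """Complementary-filter gains and reference vectors.

    kp : proportional gain, 1/s.  Larger values trust the vector
        observations more; 1.0 gives a well-damped ~1 s correction constant.
    ki : integral gain, 1/s^2.  Nonzero values reject constant residual
        gyro bias; 0 disables the integrator.
    use_magnetometer : feed the heading correction (tilt never uses mag).
    g_ref : gravity vector in the global frame, m/s^2.
    m_ref : magnetic-field direction in the global frame (any norm; only the
        horizontal component is used).
    acc_gate_g : reject the gravity correction when the accelerometer norm
        deviates from g by more than this fraction (high-dynamic frames).
    """

    kp: float = 1.0
    ki: float = 0.1
    use_magnetometer: bool = True
    g_ref: tuple[float, float, float] = (0.0, 0.0, 9.81)
    m_ref: tuple[float, float, float] = DEFAULT_M_REF
    acc_gate_g: float = 0.3

    def __post_init__(self) -> None:
        if not self.kp > 0:
            raise InvalidArgumentError("kp must be positive")
        if self.ki < 0:
            raise InvalidArgumentError("ki must be non-negative")


@dataclass
class OrientationTrack:
    """Per-frame unit quaternions (n, 4) at a fixed sample rate."""

    quats: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.quats = np.asarray(self.quats, dtype=float)
        if self.quats.ndim != 2 or self.quats.shape[1] != 4:
            raise InvalidArgumentError("quats must be (n, 4)")

    def __len__(self) -> int:
        return len(self.quats)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate

    def to_csv(self, path: str | Path) -> None:
        """Export as CSV with one w,x,y,z quaternion per row."""
        np.savetxt(path, self.quats, delimiter=",", header="w,x,y,z", comments="")


def initial_orientation(s: ImuStream, p: FilterParams | None = None,
                        n_avg: int = 10) -> np.ndarray:
    """TRIAD attitude from the first accelerometer/magnetometer samples.

    Averages the first ``n_avg`` frames and pairs the measured gravity (and,
    when enabled, magnetic) directions with their global references to build
    the body-to-global rotation.  Used to warm-start the observer so the
    static calibration window is not spent converging from identity.  Falls
    back to a gravity-only (yaw-free) attitude without a usable
    magnetometer, and to identity if the accelerometer is degenerate.
    """
    p = p or FilterParams()
    n = min(n_avg, len(s))
    acc = s.acc[:n].mean(axis=0)
    mag = s.mag[:n].mean(axis=0)
    g = np.asarray(p.g_ref, dtype=float)
    if np.linalg.norm(acc) < 1e-9 or np.linalg.norm(g) < 1e-9:
        return identity_quat()
    v1 = g / np.linalg.norm(g)
    b1 = acc / np.linalg.norm(acc)
    m_ref = np.asarray(p.m_ref, dtype=float)
    v2 = np.cross(v1, m_ref)
    b2 = np.cross(b1, mag)
    if (not p.use_magnetometer or np.linalg.norm(v2) < 1e-9
            or np.linalg.norm(b2) < 1e-9):
        # gravity-only: any horizontal direction serves as the second leg
        ref = np.array([1.0, 0.0, 0.0]) if abs(b1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        b2 = np.cross(b1, ref)
        v2 = np.cross(v1, ref)
        if np.linalg.norm(v2) < 1e-9:
            return identity_quat()
    v2 /= np.linalg.norm(v2)
    b2 /= np.linalg.norm(b2)
    Mg = np.column_stack([v1, v2, np.cross(v1, v2)])
    Mb = np.column_stack([b1, b2, np.cross(b1, b2)])
    return matrix_to_quat(Mg @ Mb.T)


def fuse(s: ImuStream, p: FilterParams | None = None,
         q0: np.ndarray | str | None = "auto") -> OrientationTrack:
    """Estimate the IMU orientation track from a bias-compensated stream.

    ``q0`` seeds the observer: ``"auto"`` (default) warm-starts from the
    first accelerometer/magnetometer samples via :func:`initial_orientation`;
    ``None`` starts at identity.  Frame 0 of the output holds ``q0`` after
    its first correction step.  Deterministic given inputs.
    """
    p = p or FilterParams()
    if s.sample_rate <= 0:
        raise InvalidArgumentError("sample_rate must be positive")
    dt = 1.0 / s.sample_rate
    g = np.asarray(p.g_ref, dtype=float)
    gnorm = np.linalg.norm(g)
    ghat = g / gnorm
    m_h = np.asarray(p.m_ref, dtype=float).copy()
    m_h[2] = 0.0
    mnorm = np.linalg.norm(m_h)
    use_mag = p.use_magnetometer and mnorm > 0
    if p.use_magnetometer and not use_mag:
        logger.warning("m_ref has no horizontal component; magnetometer disabled")
    if use_mag:
        m_h /= mnorm

    if isinstance(q0, str):
        if q0 != "auto":
            raise InvalidArgumentError(f"q0 must be 'auto', None or a quaternion, got {q0!r}")
        q = initial_orientation(s, p)
    elif q0 is not None:
        q = qnormalize(np.asarray(q0, dtype=float))
    else:
        q = identity_quat()
    integ = np.zeros(3)
    out = np.empty((len(s), 4))
    acc_all, gyr_all, mag_all = s.acc, s.gyr, s.mag
    acc_norms = np.linalg.norm(acc_all, axis=1)
    mag_norms = np.linalg.norm(mag_all, axis=1)
    gate = p.acc_gate_g * gnorm

    for i in range(len(s)):
        e = np.zeros(3)
        na = acc_norms[i]
        if na > 0.0 and abs(na - gnorm) <= gate:
            v_meas = acc_all[i] / na
            v_pred = qrotate(qconj(q), ghat)
            e += np.cross(v_meas, v_pred)
        elif na == 0.0:
            logger.debug("frame %d: zero-norm accelerometer, gyro-only step", i)
        if use_mag and mag_norms[i] > 0.0:
            # heading-only: compare horizontal projections in the global
            # frame so magnetic dip cannot corrupt tilt
            m_g = qrotate(q, mag_all[i])
            m_g[2] = 0.0
            nm = np.linalg.norm(m_g)
            if nm > 1e-12:
                e_g = np.cross(m_g / nm, m_h)
                e_g[0] = e_g[1] = 0.0  # keep only the vertical (yaw) component
                e += qrotate(qconj(q), e_g)
        integ += e * dt
        w = gyr_all[i] + p.kp * e + p.ki * integ
        dq = 0.5 * qmul(q, np.array([0.0, w[0], w[1], w[2]]))
        q = qnormalize(q + dq * dt)
        out[i] = q
    return OrientationTrack(qcanonical(out), s.sample_rate)
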