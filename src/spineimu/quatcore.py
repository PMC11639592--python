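"""Quaternion and rotation-matrix algebra for joint-angle estimation.

Conventions
-----------
* Quaternions are scalar-first ``(w, x, y, z)`` ndarrays, Hamilton
  (right-handed) product.  ``q`` and ``-q`` encode the same rotation; every
  function that returns a quaternion canonicalizes its sign to ``w >= 0``.
* A unit quaternion ``q`` maps body-frame vectors into the reference frame:
  ``v_ref = R(q) @ v_body`` with ``R = quat_to_matrix(q)``.
* Euler angles use the ZXY decomposition: the rotation factors as
  ``R = Ry(alpha) @ Rx(beta) @ Rz(gamma)`` so that

      alpha = atan2(R13, R33)   (y-axis yaw,  "rotation")
      beta  = asin(-R23)        (x-axis pitch, "abduction")
      gamma = atan2(R21, R22)   (z-axis roll, "flexion")

  The two-argument arctangent recovers the full (-180, 180] range; a
  single-argument arctan would fold exercises that cross +/-90 degrees.

All functions broadcast over leading axes, so an orientation track of shape
``(n, 4)`` is processed in one call.
"""

from __future__ import annotations

import numpy as np

from .errors import GimbalLockError, InvalidArgumentError

__all__ = [
    "qnormalize",
    "qcanonical",
    "qmul",
    "qconj",
    "qrotate",
    "quat_from_axis_angle",
    "quat_to_matrix",
    "matrix_to_quat",
    "qmean",
    "euler_zxy",
    "compose_zxy",
    "quat_angle_deg",
]

_IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def identity_quat() -> np.ndarray:
    """Return a fresh identity quaternion ``(1, 0, 0, 0)``."""
    return _IDENTITY.copy()


def _check_finite(q: np.ndarray, name: str) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise InvalidArgumentError(f"{name}: expected trailing axis of length 4, got {q.shape}")
    if not np.all(np.isfinite(q)):
        raise InvalidArgumentError(f"{name}: non-finite quaternion components")
    return q


def qnormalize(q: np.ndarray) -> np.ndarray:
    """Scale to unit norm (within 1e-9 of 1 afterwards)."""
    q = _check_finite(q, "q")
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise InvalidArgumentError("cannot normalize a zero quaternion")
    return q / n


def qcanonical(q: np.ndarray) -> np.ndarray:
    """Flip sign so the scalar part is non-negative (q and -q are one rotation)."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * sign


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a (x) b``; composes rotations (b applied first)."""
    a = _check_finite(a, "a")
    b = _check_finite(b, "b")
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    """Conjugate (negated vector part); the inverse rotation for unit input."""
    q = _check_finite(q, "q")
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q`` (sandwich q v q*)."""
    q = _check_finite(q, "q")
    v = np.asarray(v, dtype=float)
    w = q[..., 0:1]
    u = q[..., 1:4]
    # v' = v + 2w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def quat_from_axis_angle(axis: np.ndarray, angle_rad: float | np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_rad`` about ``axis``.

    ``angle_rad`` may be an array; the result then has shape ``(*angle.shape, 4)``.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0 or not np.isfinite(n):
        raise InvalidArgumentError("axis must be a finite nonzero 3-vector")
    axis = axis / n
    half = 0.5 * np.asarray(angle_rad, dtype=float)
    w = np.cos(half)
    xyz = np.sin(half)[..., None] * axis
    return np.concatenate([w[..., None], xyz], axis=-1)


def quat_to_matrix(q: np.ndarray, unit_tol: float = 1e-6) -> np.ndarray:
    """Rotation matrix of a unit quaternion; shape ``(..., 3, 3)``.

    Raises
    ------
    InvalidArgumentError
        If the input norm deviates from 1 by more than ``unit_tol``.
    """
    q = _check_finite(q, "q")
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > unit_tol):
        raise InvalidArgumentError(
            f"quaternion norm deviates from 1 by more than {unit_tol:g}"
        )
    w, x, y, z = (q[..., i] for i in range(4))
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Unit quaternion of a rotation matrix (Shepperd's method), w >= 0."""
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise InvalidArgumentError(f"expected (..., 3, 3) matrix, got {R.shape}")
    # Branch on the largest of (trace, R00, R11, R22) for numerical safety.
    t = np.einsum("...ii->...", R)
    q = np.empty(R.shape[:-2] + (4,))
    flat_R = R.reshape(-1, 3, 3)
    flat_q = q.reshape(-1, 4)
    flat_t = np.atleast_1d(t).reshape(-1)
    for i in range(flat_R.shape[0]):
        m = flat_R[i]
        tr = flat_t[i]
        if tr > max(m[0, 0], m[1, 1], m[2, 2]):
            s = 2.0 * np.sqrt(1.0 + tr)
            flat_q[i] = [0.25 * s, (m[2, 1] - m[1, 2]) / s,
                         (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        else:
            k = int(np.argmax([m[0, 0], m[1, 1], m[2, 2]]))
            a, b, c = k, (k + 1) % 3, (k + 2) % 3
            s = 2.0 * np.sqrt(1.0 + m[a, a] - m[b, b] - m[c, c])
            vec = np.empty(3)
            vec[a] = 0.25 * s
            vec[b] = (m[b, a] + m[a, b]) / s
            vec[c] = (m[c, a] + m[a, c]) / s
            flat_q[i] = [(m[c, b] - m[b, c]) / s, vec[0], vec[1], vec[2]]
    return qcanonical(qnormalize(q))


def qmean(quats: np.ndarray) -> np.ndarray:
    """Chordal mean quaternion: dominant eigenvector of sum(q q^T).

    Sign-robust: mixing q and -q samples does not bias the estimate.
    """
    quats = _check_finite(quats, "quats")
    if quats.ndim != 2:
        raise InvalidArgumentError("qmean expects an (n, 4) array")
    M = quats.T @ quats
    vals, vecs = np.linalg.eigh(M)
    return qcanonical(qnormalize(vecs[:, -1]))


def quat_angle_deg(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Geodesic angle (degrees) of ``a`` or, if ``b`` given, between a and b."""
    q = a if b is None else qmul(qconj(a), b)
    q = qnormalize(q)
    return np.degrees(2.0 * np.arccos(np.clip(np.abs(q[..., 0]), -1.0, 1.0)))


_GIMBAL_TOL = 1e-9


def euler_zxy(R: np.ndarray) -> tuple[float, float, float]:
    """ZXY Euler angles (alpha, beta, gamma) in degrees of one rotation matrix.

    alpha (y-axis yaw) and gamma (z-axis roll) lie in (-180, 180]; beta
    (x-axis pitch) in [-90, 90].

    Raises
    ------
    GimbalLockError
        When |R23| >= 1 - 1e-9 (|beta| = 90 deg) and yaw/roll degenerate.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidArgumentError("euler_zxy expects a single 3x3 matrix")
    s = -R[1, 2]
    if abs(s) >= 1.0 - _GIMBAL_TOL:
        raise GimbalLockError(np.degrees(np.arcsin(np.clip(s, -1.0, 1.0))))
    alpha = np.degrees(np.arctan2(R[0, 2], R[2, 2]))
    beta = np.degrees(np.arcsin(s))
    gamma = np.degrees(np.arctan2(R[1, 0], R[1, 1]))
    return float(alpha), float(beta), float(gamma)


def euler_zxy_track(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ZXY extraction over ``(n, 3, 3)`` matrices.

    Returns ``(alpha, beta, gamma, gimbal_mask)`` in degrees.  Frames inside
    the gimbal-lock band are flagged in ``gimbal_mask`` (caller decides how to
    handle them) with alpha/gamma computed from the clipped sine.
    """
    R = np.asarray(R, dtype=float)
    s = np.clip(-R[..., 1, 2], -1.0, 1.0)
    gimbal = np.abs(s) >= 1.0 - _GIMBAL_TOL
    alpha = np.degrees(np.arctan2(R[..., 0, 2], R[..., 2, 2]))
    beta = np.degrees(np.arcsin(s))
    gamma = np.degrees(np.arctan2(R[..., 1, 0], R[..., 1, 1]))
    return alpha, beta, gamma, gimbal


def compose_zxy(alpha_deg: float, beta_deg: float, gamma_deg: float) -> np.ndarray:
    """Inverse of :func:`euler_zxy`: build ``Ry(alpha) @ Rx(beta) @ Rz(gamma)``."""
    a, b, g = np.radians([alpha_deg, beta_deg, gamma_deg])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    Ry = np.array([[ca, 0, sa], [0, 1, 0], [-sa, 0, ca]])
    Rx = np.array([[1, 0, 0], [0, cb, -sb], [0, sb, cb]])
    Rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return Ry @ Rx @ Rz
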