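"""Quaternion/rotation algebra against independent oracles.

scipy.spatial.transform.Rotation serves as the external cross-check for the
hand-written algebra; the ZXY Euler extraction is checked by recomposition.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spineimu.errors import GimbalLockError, InvalidArgumentError
from spineimu.quatcore import (compose_zxy, euler_zxy, identity_quat,
                               matrix_to_quat, qcanonical, qconj, qmean, qmul,
                               qnormalize, qrotate, quat_from_axis_angle,
                               quat_to_matrix)

IDENT = np.array([1.0, 0.0, 0.0, 0.0])


def random_unit_quats(rng, n):
    return qnormalize(rng.standard_normal((n, 4)))


def to_scipy(q):
    return Rotation.from_quat(np.roll(np.atleast_2d(q), -1, axis=-1))


class TestProduct:
    def test_identity_element(self, rng):
        q = random_unit_quats(rng, 5)
        np.testing.assert_allclose(qmul(IDENT, q), q, atol=1e-15)
        np.testing.assert_allclose(qmul(q, IDENT), q, atol=1e-15)

    def test_conjugate_is_inverse(self, rng):
        q = random_unit_quats(rng, 5)
        np.testing.assert_allclose(qcanonical(qmul(q, qconj(q))),
                                   np.tile(IDENT, (5, 1)), atol=1e-12)

    def test_against_matrix_product_oracle(self):
        a = quat_from_axis_angle([0, 0, 1], np.pi / 2)
        b = quat_from_axis_angle([1, 0, 0], np.pi / 2)
        R_oracle = quat_to_matrix(a) @ quat_to_matrix(b)
        np.testing.assert_allclose(quat_to_matrix(qmul(a, b)), R_oracle, atol=1e-12)

    def test_norm_multiplicativity(self, rng):
        a = rng.standard_normal((200, 4))
        b = rng.standard_normal((200, 4))
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        np.testing.assert_allclose(np.linalg.norm(qmul(a, b), axis=1),
                                   na * nb, rtol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            qmul(np.array([np.nan, 0, 0, 0]), IDENT)


class TestConjugate:
    def test_identity_and_involution(self, rng):
        np.testing.assert_array_equal(qconj(IDENT), IDENT)
        q = random_unit_quats(rng, 10)
        np.testing.assert_array_equal(qconj(qconj(q)), q)

    def test_inverse_rotation_roundtrip(self, rng):
        q = random_unit_quats(rng, 50)
        v = rng.standard_normal((50, 3))
        np.testing.assert_allclose(qrotate(qconj(q), qrotate(q, v)), v, atol=1e-12)


class TestQuatToMatrix:
    def test_identity(self):
        np.testing.assert_allclose(quat_to_matrix(IDENT), np.eye(3), atol=1e-15)

    def test_half_turn_about_z(self):
        q = quat_from_axis_angle([0, 0, 1], np.pi)
        np.testing.assert_allclose(quat_to_matrix(q), np.diag([-1.0, -1.0, 1.0]),
                                   atol=1e-15)

    def test_matrix_action_matches_sandwich(self, rng):
        q = random_unit_quats(rng, 50)
        v = rng.standard_normal((50, 3))
        R = quat_to_matrix(q)
        np.testing.assert_allclose(np.einsum("nij,nj->ni", R, v),
                                   qrotate(q, v), atol=1e-12)

    def test_homomorphism_1000_pairs(self, rng):
        a = random_unit_quats(rng, 1000)
        b = random_unit_quats(rng, 1000)
        lhs = quat_to_matrix(qmul(a, b))
        rhs = np.einsum("nij,njk->nik", quat_to_matrix(a), quat_to_matrix(b))
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    def test_non_unit_rejected(self):
        with pytest.raises(InvalidArgumentError):
            quat_to_matrix(2.0 * IDENT)

    def test_agrees_with_scipy(self, rng):
        q = random_unit_quats(rng, 20)
        np.testing.assert_allclose(quat_to_matrix(q), to_scipy(q).as_matrix(),
                                   atol=1e-12)


class TestMatrixToQuat:
    def test_roundtrip(self, rng):
        q = qcanonical(random_unit_quats(rng, 100))
        np.testing.assert_allclose(matrix_to_quat(quat_to_matrix(q)), q, atol=1e-9)


class TestEulerZXY:
    def test_identity(self):
        assert euler_zxy(np.eye(3)) == (0.0, 0.0, 0.0)

    def test_pure_roll_is_gamma(self):
        R = quat_to_matrix(quat_from_axis_angle([0, 0, 1], np.radians(30)))
        a, b, g = euler_zxy(R)
        np.testing.assert_allclose([a, b, g], [0.0, 0.0, 30.0], atol=1e-12)

    def test_roundtrip_random_triples(self, rng):
        alphas = rng.uniform(-179, 179, 300)
        betas = rng.uniform(-85, 85, 300)
        gammas = rng.uniform(-179, 179, 300)
        for a, b, g in zip(alphas, betas, gammas):
            out = euler_zxy(compose_zxy(a, b, g))
            np.testing.assert_allclose(out, (a, b, g), atol=1e-6)

    def test_quadrants_beyond_90(self):
        # single-argument arctan would fold these into (-90, 90)
        for g in (120.0, -150.0, 179.0):
            out = euler_zxy(compose_zxy(0.0, 0.0, g))
            np.testing.assert_allclose(out[2], g, atol=1e-9)

    def test_gimbal_lock_raises_with_degenerate_beta(self):
        R = compose_zxy(0.0, 90.0, 0.0)
        with pytest.raises(GimbalLockError) as exc:
            euler_zxy(R)
        assert abs(exc.value.beta_deg - 90.0) < 1e-6


class TestMean:
    def test_constant_track(self, rng):
        q0 = qcanonical(random_unit_quats(rng, 1)[0])
        quats = np.tile(q0, (20, 1))
        np.testing.assert_allclose(qmean(quats), q0, atol=1e-12)

    def test_sign_robust(self, rng):
        q0 = qcanonical(random_unit_quats(rng, 1)[0])
        quats = np.tile(q0, (20, 1))
        quats[::2] *= -1.0
        np.testing.assert_allclose(qmean(quats), q0, atol=1e-12)

    def test_small_noise_near_truth(self, rng):
        from spineimu.quatcore import quat_angle_deg

        q0 = qcanonical(random_unit_quats(rng, 1)[0])
        errs = []
        for _ in range(50):
            axes = rng.standard_normal((300, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            angles = rng.normal(0, np.radians(1.0), 300)
            perturb = np.concatenate(
                [np.cos(angles / 2)[:, None], np.sin(angles / 2)[:, None] * axes],
                axis=1)
            errs.append(float(quat_angle_deg(qmean(qmul(q0, perturb)), q0)))
        assert np.mean(errs) < 0.5
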