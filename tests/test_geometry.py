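import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from macromol.geometry import (RigidTransform, apply_transform, rmsd,
                               superpose)


def random_rigid(rng) -> RigidTransform:
    R = Rotation.random(random_state=rng).as_matrix()
    return RigidTransform(R, rng.normal(0, 10, 3))


class TestRmsd:
    def test_identical_is_zero(self):
        a = np.random.default_rng(0).normal(size=(10, 3))
        assert rmsd(a, a) == 0.0

    def test_single_pair_distance(self):
        assert rmsd([[0, 0, 0]], [[3, 4, 0]]) == pytest.approx(5.0)

    def test_three_point_hand_calculation(self):
        # displacements (1,0,0), (0,2,0), (0,0,2): mean sq = (1+4+4)/3 = 3
        a = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], dtype=float)
        b = a + np.array([[1, 0, 0], [0, 2, 0], [0, 0, 2]])
        assert rmsd(a, b) == pytest.approx(np.sqrt(3.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestSuperpose:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        t, r = superpose(pts, pts)
        assert r < 1e-12
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)

    def test_recovers_constructed_motion(self):
        rng = np.random.default_rng(2)
        fixed = rng.normal(size=(20, 3))
        ang = np.pi / 2
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                       [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        moving = fixed @ Rz.T + np.array([1.0, 2.0, 3.0])
        t, r = superpose(fixed, moving)
        assert r < 1e-9
        np.testing.assert_allclose(apply_transform(t, moving), fixed,
                                   atol=1e-9)

    def test_rmsd_matches_gradient_free_minimizer(self):
        """Kabsch optimum equals direct numeric minimization over the
        6-parameter rigid-motion space (independent oracle)."""
        rng = np.random.default_rng(3)
        fixed = rng.normal(size=(50, 3)) * 5
        moving = rng.normal(size=(50, 3)) * 5

        def objective(params):
            R = Rotation.from_rotvec(params[:3]).as_matrix()
            return rmsd(fixed, moving @ R.T + params[3:])

        t, kabsch_r = superpose(fixed, moving)
        x0 = np.concatenate([Rotation.from_matrix(t.rotation).as_rotvec(),
                             t.translation])
        best = min(
            minimize(objective, x0 + rng.normal(0, 0.1, 6),
                     method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-14,
                              "maxiter": 20000}).fun
            for _ in range(3))
        assert kabsch_r <= best + 1e-6
        assert abs(kabsch_r - best) < 1e-6

    def test_reflection_excluded(self):
        rng = np.random.default_rng(4)
        fixed = rng.normal(size=(10, 3))
        moving = fixed.copy()
        moving[:, 0] *= -1  # mirrored set
        t, _ = superpose(fixed, moving)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_premotion_of_moving(self):
        rng = np.random.default_rng(5)
        fixed = rng.normal(size=(15, 3))
        moving = rng.normal(size=(15, 3))
        _, r0 = superpose(fixed, moving)
        for seed in range(5):
            g = np.random.default_rng(seed)
            _, r1 = superpose(fixed, apply_transform(random_rigid(g), moving))
            assert r1 == pytest.approx(r0, abs=1e-9)

    def test_plain_rmsd_bounds_superposed_rmsd(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = rng.normal(size=(12, 3))
            b = rng.normal(size=(12, 3))
            _, rs = superpose(a, b)
            assert rmsd(a, b) >= rs - 1e-12

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTransformAlgebra:
    def test_identity_leaves_input(self):
        x = np.random.default_rng(7).normal(size=(5, 3))
        np.testing.assert_array_equal(
            apply_transform(RigidTransform.identity(), x), x)

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(8)
        t = random_rigid(rng)
        x = rng.normal(size=(6, 3))
        np.testing.assert_allclose(
            apply_transform(t, apply_transform(t.inverse(), x)), x,
            atol=1e-12)

    def test_rotation_composition(self):
        def rot_z(deg):
            a = np.radians(deg)
            return RigidTransform(
                np.array([[np.cos(a), -np.sin(a), 0],
                          [np.sin(a), np.cos(a), 0], [0, 0, 1]]), np.zeros(3))

        r120 = rot_z(120)
        r240 = rot_z(240)
        np.testing.assert_allclose(r120.compose(r120).rotation,
                                   r240.rotation, atol=1e-12)

    def test_rotation_angle_and_axis(self):
        a = np.radians(90)
        t = RigidTransform(np.array([[np.cos(a), -np.sin(a), 0],
                                     [np.sin(a), np.cos(a), 0],
                                     [0, 0, 1]]), np.zeros(3))
        assert t.rotation_angle == pytest.approx(90.0)
        np.testing.assert_allclose(np.abs(t.rotation_axis), [0, 0, 1],
                                   atol=1e-9)

    def test_reflection_rejected_by_constructor(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
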