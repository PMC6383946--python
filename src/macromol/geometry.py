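"""Rigid-body superposition, RMSD and transform algebra.

Superposition uses the Kabsch algorithm (SVD with determinant correction so
that only proper rotations are returned).  Transforms are affine maps
``y = R @ x + t`` with ``R`` a proper rotation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = ["RigidTransform", "superpose", "apply_transform", "rmsd"]

_ORTHO_TOL = 1e-9


class RigidTransform:
    """A proper rigid motion: rotation matrix plus translation vector."""

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation, translation):
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")
        self.rotation = R
        self.translation = t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords):
        return apply_transform(self, coords)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def rotation_angle(self) -> float:
        """Rotation angle in degrees, in [0, 180]."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    @property
    def rotation_axis(self) -> Optional[np.ndarray]:
        """Unit rotation axis, or None for the identity rotation."""
        w, v = np.linalg.eig(self.rotation)
        i = int(np.argmin(np.abs(w - 1.0)))
        axis = np.real(v[:, i])
        n = np.linalg.norm(axis)
        if self.rotation_angle < 1e-6 or n == 0:
            return None
        axis = axis / n
        # orient so that the rotation about +axis has positive angle
        test = np.array([1.0, 0.22, -0.41])
        test -= axis * (test @ axis)
        if np.linalg.norm(test) > 1e-8:
            rotated = self.rotation @ test
            if axis @ np.cross(test, rotated) < 0:
                axis = -axis
        return axis

    def __repr__(self) -> str:
        return (f"RigidTransform(angle={self.rotation_angle:.2f} deg, "
                f"t={np.round(self.translation, 3)})")


def apply_transform(t: RigidTransform, coords):
    """Apply ``y = R x + t`` to a 3-vector or an (n, 3) array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        return t.rotation @ coords + t.translation
    return coords @ t.rotation.T + t.translation


def rmsd(a, b) -> float:
    """Root-mean-square deviation of paired coordinates, no superposition."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape or a.shape[0] < 1:
        raise ValueError(f"coordinate arrays must match: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(fixed, moving) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns the optimal proper rigid transform T and the residual RMSD of
    ``T(moving)`` against ``fixed``.  Reflections are excluded by flipping
    the sign of the smallest singular vector when needed (Kabsch).
    Collinear point sets still return a valid minimizer; the rotation
    about the degenerate axis is then chosen arbitrarily by the SVD.
    """
    P = np.asarray(fixed, dtype=float)
    Q = np.asarray(moving, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("fixed and moving must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    transform = RigidTransform(R, t)
    return transform, rmsd(P, apply_transform(transform, Q))
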