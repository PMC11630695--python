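"""Rigid transforms and axis-angle decompositions.

All coordinates are millimetres, all angles degrees.  Rotations are proper
(right-handed, determinant +1) and validated to a tolerance of 1e-9; the
principal axis-angle decomposition follows the reporting convention used
throughout the package: the axis is flipped so that its z-component is
non-negative (ties broken by y >= 0, then x >= 0), which leaves the angle in
[0, 180) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidTransformError

ORTHONORMALITY_TOL = 1e-9


def _check_rotation(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise InvalidTransformError(f"rotation must be 3x3, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise InvalidTransformError("rotation contains non-finite entries")
    if not np.allclose(m.T @ m, np.eye(3), atol=tol):
        raise InvalidTransformError("rotation is not orthonormal")
    if np.linalg.det(m) < 0:
        raise InvalidTransformError("rotation has determinant -1 (reflection)")
    return m


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise InvalidTransformError("translation contains non-finite entries")
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg, center=None, translation=None) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis``.

        With ``center`` given, the rotation axis passes through that point;
        otherwise it passes through the origin.  An extra ``translation`` is
        applied after the rotation.
        """
        a = np.asarray(axis, dtype=float).reshape(3)
        norm = np.linalg.norm(a)
        if norm == 0:
            raise InvalidTransformError("rotation axis must be nonzero")
        a = a / norm
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * a).as_matrix()
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        if center is not None:
            c = np.asarray(center, dtype=float).reshape(3)
            t = t + c - rot @ c
        return cls(rot, t)

    @classmethod
    def from_quaternion_wxyz(cls, quat_wxyz, translation) -> "RigidTransform":
        w, x, y, z = quat_wxyz
        rot = Rotation.from_quat([x, y, z, w]).as_matrix()
        return cls(rot, translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array or a single 3-vector through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def quaternion_wxyz(self) -> np.ndarray:
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        if w < 0:  # canonical hemisphere for serialization
            x, y, z, w = -x, -y, -z, -w
        return np.array([w, x, y, z])

    def rotation_angle_deg(self) -> float:
        return float(np.rad2deg(Rotation.from_matrix(self.rotation).magnitude()))

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


@dataclass(frozen=True)
class AxisAngle:
    """Principal rotation axis (unit) and angle in degrees, angle in [0, 180)."""

    axis: np.ndarray
    angle_deg: float

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float).reshape(3)
        n = np.linalg.norm(a)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("axis must be unit length")
        object.__setattr__(self, "axis", a / n)

    def matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(np.deg2rad(self.angle_deg) * self.axis).as_matrix()


def canonical_axis(axis: np.ndarray) -> np.ndarray:
    """Flip an axis so z >= 0; ties broken by y >= 0, then x >= 0."""
    a = np.asarray(axis, dtype=float)
    z_tol = 1e-12
    if a[2] < -z_tol:
        return -a
    if abs(a[2]) <= z_tol:
        if a[1] < -z_tol:
            return -a
        if abs(a[1]) <= z_tol and a[0] < 0:
            return -a
    return a


DEFAULT_IDENTITY_AXIS = np.array([0.0, 0.0, 1.0])


def rotation_to_axis_angle(rotation: np.ndarray) -> AxisAngle:
    """Principal axis-angle decomposition with the z >= 0 axis convention.

    The identity (angle below ~1e-9 deg) returns angle 0 with the default
    axis (0, 0, 1) since its axis is undefined.
    """
    rot = _check_rotation(rotation)
    rv = Rotation.from_matrix(rot).as_rotvec()
    angle = np.linalg.norm(rv)
    if angle < 1e-12:
        return AxisAngle(DEFAULT_IDENTITY_AXIS, 0.0)
    axis = rv / angle
    return AxisAngle(canonical_axis(axis), float(np.rad2deg(angle)))


def unit(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return a / n


def perpendicular_unit(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    v = unit(v)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    return unit(np.cross(v, ref))
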