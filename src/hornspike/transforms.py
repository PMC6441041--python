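"""Rigid-body transforms in physical (Å) coordinates.

Rotations are proper 3×3 matrices; Euler angles use the intrinsic ZYZ
convention (rot, tilt, psi) in degrees, the dominant convention in
single-particle cryo-EM software.  A :class:`RigidTransform` maps motif-frame
coordinates (Å, about an explicit centre) into map-frame coordinates:
``x_map = R @ u + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "euler_to_matrix",
    "matrix_to_euler",
    "geodesic_angle_deg",
    "is_rotation_matrix",
]

_ROT_TOL = 1e-6


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic Euler angles (degrees) → 3×3 rotation matrix."""
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """3×3 rotation matrix → ZYZ intrinsic Euler angles (rot, tilt, psi) in degrees."""
    import warnings

    with warnings.catch_warnings():
        # tilt 0/180 is a legitimate gimbal-lock case; the convention sets
        # the redundant angle to zero
        warnings.simplefilter("ignore", UserWarning)
        rot, tilt, psi = Rotation.from_matrix(R).as_euler("ZYZ", degrees=True)
    return float(rot), float(tilt), float(psi)


def is_rotation_matrix(R: np.ndarray, tol: float = _ROT_TOL) -> bool:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    return (
        np.allclose(R.T @ R, np.eye(3), atol=10 * tol)
        and abs(np.linalg.det(R) - 1.0) < 10 * tol
    )


def geodesic_angle_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic (rotation-angle) distance between two rotations, degrees."""
    c = (np.trace(np.asarray(Ra).T @ np.asarray(Rb)) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, acting as ``x -> R @ x + t`` (Å)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not is_rotation_matrix(R):
            raise ValueError(
                "rotation must be a proper rotation matrix (det=+1, orthonormal)"
            )
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(
        cls, rot: float, tilt: float, psi: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        return cls(euler_to_matrix(rot, tilt, psi), np.asarray(translation, float))

    @classmethod
    def about_axis(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("rotation axis must be non-zero")
        R = Rotation.from_rotvec(np.radians(angle_deg) * axis / n).as_matrix()
        return cls(R, np.asarray(translation, float))

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of Å coordinates."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    # -- views -------------------------------------------------------------
    @property
    def euler_deg(self) -> tuple[float, float, float]:
        """(rot, tilt, psi) ZYZ intrinsic, degrees."""
        return matrix_to_euler(self.rotation)

    @property
    def rotvec(self) -> np.ndarray:
        """Axis-angle vector (radians·axis)."""
        return Rotation.from_matrix(self.rotation).as_rotvec()

    def rotation_angle_deg(self) -> float:
        return geodesic_angle_deg(np.eye(3), self.rotation)

    def twist_about_axis_deg(self, axis) -> float:
        """Rotation component (twist) of this transform's rotation about ``axis``.

        Twist–swing decomposition via the quaternion: the twist about unit
        axis n is ``2·atan2(q_vec·n, q_w)``, folded into [0°, 180°].
        """
        n = np.asarray(axis, dtype=float)
        n = n / np.linalg.norm(n)
        q = Rotation.from_matrix(self.rotation).as_quat()  # (x, y, z, w)
        twist = 2.0 * np.degrees(np.arctan2(float(q[:3] @ n), float(q[3])))
        twist = abs(((twist + 180.0) % 360.0) - 180.0)
        return float(twist)

    def is_close(self, other: "RigidTransform", atol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        r, t, p = self.euler_deg
        x, y, z = self.translation
        return (
            f"RigidTransform(euler=({r:.2f}, {t:.2f}, {p:.2f})°, "
            f"t=({x:.2f}, {y:.2f}, {z:.2f}) Å)"
        )
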