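"""Rigid transforms (nail frame -> camera frame)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class Pose:
    """Proper rigid transform mapping nail-frame points into the camera frame.

    ``rotation`` is a 3x3 proper orthonormal matrix (det +1 within 1e-9),
    ``translation_mm`` a 3-vector.
    """

    rotation: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if np.linalg.norm(R @ R.T - np.eye(3)) > 1e-9 or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthonormal (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation_mm", t)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_quaternion(cls, q_xyzw, translation_mm) -> "Pose":
        return cls(Rotation.from_quat(np.asarray(q_xyzw, dtype=float)).as_matrix(),
                   translation_mm)

    @classmethod
    def from_axis_angle(cls, rotvec, translation_mm) -> "Pose":
        return cls(Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix(),
                   translation_mm)

    # -- algebra -----------------------------------------------------------

    def apply(self, points) -> np.ndarray:
        """Transform one point or an ``(n, 3)`` array of points."""
        p = np.asarray(points, dtype=float)
        if p.ndim == 1:
            return self.rotation @ p + self.translation_mm
        return p @ self.rotation.T + self.translation_mm[None, :]

    def apply_direction(self, d) -> np.ndarray:
        return self.rotation @ np.asarray(d, dtype=float)

    def compose(self, other: "Pose") -> "Pose":
        """``self o other`` (apply ``other`` first)."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation_mm + self.translation_mm)

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation_mm)

    def perturbed(self, rotvec, dt) -> "Pose":
        """Left-compose a small rotation and add a translation increment."""
        dR = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        return Pose(dR @ self.rotation, self.translation_mm + np.asarray(dt, dtype=float))

    # -- serialization -----------------------------------------------------

    @property
    def quaternion_xyzw(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_quat()

    @property
    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()

    def to_dict(self) -> dict:
        return {
            "quaternion_xyzw": [float(x) for x in self.quaternion_xyzw],
            "translation_mm": [float(x) for x in self.translation_mm],
            # exact matrix kept alongside: the quaternion round trip is not
            # bit-identical, which would break re-rendering reproducibility
            "rotation_matrix": [[float(x) for x in row] for row in self.rotation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        if "rotation_matrix" in d:
            return cls(np.array(d["rotation_matrix"]), d["translation_mm"])
        return cls.from_quaternion(d["quaternion_xyzw"], d["translation_mm"])


def rotation_between(a, b) -> np.ndarray:
    """Smallest rotation matrix taking unit vector ``a`` to unit vector ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a
        seed = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, seed)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = v / np.linalg.norm(v)
    angle = np.arctan2(np.linalg.norm(v), c)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def angle_between_deg(a, b, directed: bool = True) -> float:
    """Angle between two vectors in degrees; undirected treats them as lines."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
    if not directed:
        c = abs(c)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
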