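"""Rigid-body pose arithmetic: unit quaternions and frames.

Conventions (used everywhere in the package): right-handed world frame with
+x the direction of motion, +z up, the sagittal plane is x-z and all hinge
axes are +y.  Quaternions are stored scalar-first ``(w, x, y, z)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pose",
    "quat_identity",
    "quat_multiply",
    "quat_normalize",
    "quat_from_rotvec",
    "quat_to_matrix",
    "rotvec_from_matrix",
    "rot_x",
    "rot_y",
    "rot_z",
]


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def quat_normalize(q: np.ndarray) -> np.ndarray:
    return np.asarray(q, dtype=float) / np.linalg.norm(q)


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 ∘ q2 (apply q2 first, then q1)."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v)
    if theta < 1e-14:
        # second-order small-angle expansion keeps the map smooth near zero
        return quat_normalize(np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]]))
    axis = v / theta
    s = np.sin(0.5 * theta)
    return np.array([np.cos(0.5 * theta), s * axis[0], s * axis[1], s * axis[2]])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotvec_from_matrix(R: np.ndarray) -> np.ndarray:
    """Logarithm of a rotation matrix (axis * angle)."""
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    s = np.linalg.norm(w)
    if s < 1e-12:
        if theta < 1.0:  # near identity
            return 0.5 * w
        # near pi: fall back to eigen decomposition
        eigval, eigvec = np.linalg.eigh(R + R.T)
        axis = eigvec[:, np.argmax(eigval)]
        axis /= np.linalg.norm(axis)
        return theta * axis
    return (theta / s) * w


def rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def quat_from_matrix(R: np.ndarray) -> np.ndarray:
    """Shepperd's method; returns (w, x, y, z) with w >= 0."""
    m00, m01, m02 = R[0]
    m10, m11, m12 = R[1]
    m20, m21, m22 = R[2]
    tr = m00 + m11 + m22
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2.0
        q = np.array([0.25 * s, (m21 - m12) / s, (m02 - m20) / s, (m10 - m01) / s])
    elif m00 >= m11 and m00 >= m22:
        s = np.sqrt(1.0 + m00 - m11 - m22) * 2.0
        q = np.array([(m21 - m12) / s, 0.25 * s, (m01 + m10) / s, (m02 + m20) / s])
    elif m11 >= m22:
        s = np.sqrt(1.0 + m11 - m00 - m22) * 2.0
        q = np.array([(m02 - m20) / s, (m01 + m10) / s, 0.25 * s, (m12 + m21) / s])
    else:
        s = np.sqrt(1.0 + m22 - m00 - m11) * 2.0
        q = np.array([(m10 - m01) / s, (m02 + m20) / s, (m12 + m21) / s, 0.25 * s])
    if q[0] < 0:
        q = -q
    return quat_normalize(q)


@dataclass
class Pose:
    """Position + unit quaternion of a body-fixed frame in the world."""

    p: np.ndarray = field(default_factory=lambda: np.zeros(3))
    q: np.ndarray = field(default_factory=quat_identity)
    _R: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)

    @property
    def R(self) -> np.ndarray:
        if self._R is None:
            self._R = quat_to_matrix(self.q)
        return self._R

    @staticmethod
    def identity() -> "Pose":
        return Pose()

    @staticmethod
    def from_matrix(R: np.ndarray, p: np.ndarray) -> "Pose":
        pose = Pose(np.asarray(p, float), quat_from_matrix(np.asarray(R, float)))
        pose._R = np.asarray(R, float)
        return pose

    def transform(self, pts: np.ndarray) -> np.ndarray:
        """Body-frame points -> world frame."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.R.T + self.p

    def inverse_transform(self, pts: np.ndarray) -> np.ndarray:
        """World-frame points -> body frame."""
        pts = np.asarray(pts, dtype=float)
        return (pts - self.p) @ self.R

    def rotate(self, vecs: np.ndarray) -> np.ndarray:
        return np.asarray(vecs, dtype=float) @ self.R.T

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other: ``other`` expressed relative to ``self``'s frame."""
        return Pose(self.p + self.R @ other.p, quat_normalize(quat_multiply(self.q, other.q)))

    def copy(self) -> "Pose":
        return Pose(self.p.copy(), self.q.copy())
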