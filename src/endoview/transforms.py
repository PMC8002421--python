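"""Rotation representations and the 7-DoF similarity transform.

A similarity transform maps points between the map frames of two cameras:

    x  ->  s * R @ x + t

with ``R`` a proper rotation, ``s > 0`` a uniform scale and ``t`` a
translation.  Rotations are carried interchangeably as 3x3 matrices, unit
quaternions ``(e0, e1, e2, e3)`` (scalar first) and axis-angle rotation
vectors ``omega`` whose norm is the rotation angle in radians.

Quaternions live on a double cover: ``q`` and ``-q`` encode the same
rotation.  Every quaternion returned by this module is *canonicalized* to
the hemisphere ``e0 >= 0`` (ties broken by the first nonzero component
being positive), which is what makes component-wise medians and means of
candidate quaternions meaningful downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import ValidationError

__all__ = [
    "SimilarityTransform",
    "canonicalize_quaternion",
    "quaternion_to_matrix",
    "matrix_to_quaternion",
    "matrix_to_rotvec",
    "rotvec_to_matrix",
    "quaternion_to_rotvec",
    "rotvec_to_quaternion",
    "rotation_angle_deg",
    "validate_rotation",
]

_ORTHO_TOL = 1e-8


def canonicalize_quaternion(q: np.ndarray) -> np.ndarray:
    """Normalize to unit length and flip into the canonical hemisphere.

    Works on a single quaternion ``(4,)`` or a stack ``(n, 4)``; scalar-first
    convention.  Canonical means ``e0 >= 0``, with sign ties resolved by the
    first nonzero component being positive.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    norms = np.linalg.norm(q, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValidationError("zero quaternion cannot be normalized")
    q = q / norms
    # sign of first nonzero component per row
    sign = np.ones(len(q))
    for col in range(4):
        undecided = sign == 1.0
        nz = np.abs(q[:, col]) > 0
        flip = undecided & nz & (q[:, col] < 0)
        keep = undecided & nz & (q[:, col] > 0)
        sign[flip] = -1.0
        sign[keep] = 2.0  # mark decided-positive
    sign[sign == 2.0] = 1.0
    q = q * sign[:, None]
    return q[0] if single else q


def _as_scipy(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(np.atleast_2d(q), -1, axis=1))


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternion(s) -> 3x3 rotation matrix (or stack)."""
    q = np.asarray(q, dtype=float)
    m = _as_scipy(q).as_matrix()
    return m[0] if q.ndim == 1 else m


def matrix_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Rotation matrix -> canonical scalar-first unit quaternion."""
    validate_rotation(R)
    q = Rotation.from_matrix(R).as_quat()
    return canonicalize_quaternion(np.roll(q, 1, axis=-1))


def matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    validate_rotation(R)
    return Rotation.from_matrix(R).as_rotvec()


def rotvec_to_matrix(omega: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(omega, dtype=float)).as_matrix()


def quaternion_to_rotvec(q: np.ndarray) -> np.ndarray:
    return _as_scipy(q).as_rotvec()[0] if np.asarray(q).ndim == 1 else \
        _as_scipy(q).as_rotvec()


def rotvec_to_quaternion(omega: np.ndarray) -> np.ndarray:
    q = Rotation.from_rotvec(np.asarray(omega, dtype=float)).as_quat()
    return canonicalize_quaternion(np.roll(q, 1, axis=-1))


def rotation_angle_deg(omega: np.ndarray) -> float:
    """Rotation angle theta = ||omega|| reported in degrees."""
    return float(np.degrees(np.linalg.norm(np.asarray(omega, dtype=float))))


def validate_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    """Check orthogonality and det +1; returns R as an ndarray."""
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValidationError(f"rotation matrix must be 3x3, got {R.shape}")
    err = np.abs(R @ np.swapaxes(R, -1, -2) - np.eye(3)).max()
    if err > tol:
        raise ValidationError(f"matrix is not orthogonal (max |R R^T - I| = {err:.3g})")
    if np.any(np.linalg.det(R) < 0):
        raise ValidationError("matrix has determinant -1 (reflection)")
    return R


@dataclass
class SimilarityTransform:
    """Rotation + uniform scale + translation: ``x -> s * R @ x + t``.

    Parameters
    ----------
    R : (3, 3) ndarray
        Proper rotation matrix.
    s : float
        Scale factor, strictly positive.
    t : (3,) ndarray
        Translation, in scene units.
    """

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    s: float = 1.0
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.R = validate_rotation(self.R)
        self.s = float(self.s)
        if not self.s > 0:
            raise ValidationError(f"scale must be > 0, got {self.s}")
        self.t = np.asarray(self.t, dtype=float).reshape(3)

    # -- algebra -------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform a point ``(3,)`` or a cloud ``(n, 3)``."""
        pts = np.asarray(points, dtype=float)
        return self.s * pts @ self.R.T + self.t

    __call__ = apply

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.R.T
        sinv = 1.0 / self.s
        return SimilarityTransform(Rinv, sinv, -sinv * Rinv @ self.t)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return SimilarityTransform(
            self.R @ other.R, self.s * other.s,
            self.s * self.R @ other.t + self.t,
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    # -- representations ----------------------------------------------
    @property
    def quaternion(self) -> np.ndarray:
        return matrix_to_quaternion(self.R)

    @property
    def rotvec(self) -> np.ndarray:
        return matrix_to_rotvec(self.R)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix of the transform."""
        M = np.eye(4)
        M[:3, :3] = self.s * self.R
        M[:3, 3] = self.t
        return M

    def to_dict(self) -> dict:
        return {
            "quaternion": self.quaternion.tolist(),
            "scale": self.s,
            "translation": self.t.tolist(),
            "matrix": self.matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            quaternion_to_matrix(np.asarray(d["quaternion"], dtype=float)),
            float(d["scale"]),
            np.asarray(d["translation"], dtype=float),
        )

    def __repr__(self):
        return (f"SimilarityTransform(s={self.s:.6g}, "
                f"rotvec={np.round(self.rotvec, 6).tolist()}, "
                f"t={np.round(self.t, 6).tolist()})")
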