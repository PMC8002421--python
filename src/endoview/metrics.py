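"""Quantitative evaluation measures.

Image similarity: zero-mean normalized cross-correlation (ZNCC, in
[-1, 1], 1 for identical images) and mutual information (MI, bits, from
the 256x256 joint intensity histogram).  Transform accuracy: axis-angle
rotation vectors, the angle between rotation vectors

    a = arccos( omega . omega' / (|omega| |omega'|) )

in degrees, and paired point-cloud mean squared error.  ``ErrorReport``
mirrors the nine-column comparison layout (omega_x, omega_y, omega_z,
theta, a, s, t_x, t_y, t_z) with errors computed as estimate - truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .transforms import SimilarityTransform, rotation_angle_deg

__all__ = [
    "zncc",
    "mutual_information",
    "image_entropy",
    "rotation_vector_angle",
    "cloud_mse",
    "cloud_sd",
    "ErrorReport",
    "transform_error_report",
    "to_grayscale",
]

#: ITU-R 601 luma weights for colour -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    return img


def zncc(I: np.ndarray, J: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two equal-size images.

    Invariant to gain and offset changes of either image; 1 for identical
    images, -1 for perfectly anti-correlated ones.  A constant image has
    no defined correlation and raises ``ValidationError``.
    """
    I = to_grayscale(I)
    J = to_grayscale(J)
    if I.shape != J.shape:
        raise ValidationError(f"image shapes differ: {I.shape} vs {J.shape}")
    Ic = I - I.mean()
    Jc = J - J.mean()
    denom = np.sqrt((Ic * Ic).sum() * (Jc * Jc).sum())
    if denom == 0:
        raise ValidationError("constant image: ZNCC undefined (zero variance)")
    return float((Ic * Jc).sum() / denom)


def _as_uint8(img: np.ndarray) -> np.ndarray:
    img = to_grayscale(img)
    if img.dtype == np.uint8:
        return img
    if img.max() <= 1.0 and img.min() >= 0.0:
        img = img * 255.0
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def mutual_information(I: np.ndarray, J: np.ndarray, bins: int = 256) -> float:
    """Mutual information in bits from the joint 8-bit intensity histogram.

    ``MI(I, J) = sum_ij P(i,j) log2( P(i,j) / (P(i) P(j)) )`` with the
    convention ``0 log 0 = 0``; symmetric, non-negative, and equal to the
    marginal entropy H(I) when J = I.
    """
    I8 = _as_uint8(I)
    J8 = _as_uint8(J)
    if I8.shape != J8.shape:
        raise ValidationError(f"image shapes differ: {I8.shape} vs {J8.shape}")
    H, _, _ = np.histogram2d(I8.ravel(), J8.ravel(),
                             bins=bins, range=[[0, 256], [0, 256]])
    P = H / H.sum()
    Pi = P.sum(axis=1)
    Pj = P.sum(axis=0)
    nz = P > 0
    denom = np.outer(Pi, Pj)
    return float(np.sum(P[nz] * np.log2(P[nz] / denom[nz])))


def image_entropy(I: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy of the 8-bit intensity histogram, bits."""
    I8 = _as_uint8(I)
    counts, _ = np.histogram(I8.ravel(), bins=bins, range=[0, 256])
    p = counts / counts.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def rotation_vector_angle(omega: np.ndarray, omega_est: np.ndarray) -> float:
    """Angle between two axis-angle rotation vectors, degrees in [0, 180]."""
    w = np.asarray(omega, dtype=float)
    wp = np.asarray(omega_est, dtype=float)
    nw, nwp = np.linalg.norm(w), np.linalg.norm(wp)
    if nw == 0 or nwp == 0:
        raise ValidationError("rotation vectors must be nonzero")
    return float(np.degrees(np.arccos(np.clip(w @ wp / (nw * nwp), -1.0, 1.0))))


def _paired(A, B):
    A = np.asarray(A, dtype=float).reshape(-1, 3)
    B = np.asarray(B, dtype=float).reshape(-1, 3)
    if len(A) != len(B):
        raise ValidationError(f"cloud sizes differ: {len(A)} vs {len(B)}")
    return np.sum((A - B) ** 2, axis=1)


def cloud_mse(A: np.ndarray, B: np.ndarray) -> float:
    """Mean over points of the squared Euclidean distance between pairs."""
    return float(np.mean(_paired(A, B)))


def cloud_sd(A: np.ndarray, B: np.ndarray) -> float:
    """Variance of the per-point squared distances."""
    return float(np.var(_paired(A, B)))


@dataclass
class ErrorReport:
    """Ground truth vs estimate for one similarity transform.

    ``errors[k] = estimates[k] - truths[k]`` for every scalar column;
    ``a_deg`` is the angle between the two rotation vectors (no
    ground-truth counterpart).
    """

    truths: dict
    estimates: dict
    errors: dict
    a_deg: float

    COLUMNS = ("omega_x", "omega_y", "omega_z", "theta_deg",
               "s", "t_x", "t_y", "t_z")

    def to_dict(self) -> dict:
        return {"truth": self.truths, "estimate": self.estimates,
                "error": self.errors, "a_deg": self.a_deg}

    def as_text(self, precision: int = 4) -> str:
        cols = list(self.COLUMNS)
        header = "          " + "".join(f"{c:>12}" for c in cols + ["a_deg"])
        def row(label, d, a=""):
            cells = "".join(f"{d[c]:>12.{precision}f}" for c in cols)
            return f"{label:<10}{cells}{a:>12}"
        lines = [header,
                 row("truth", self.truths),
                 row("estimate", self.estimates, f"{self.a_deg:.{precision}f}"),
                 row("error", self.errors)]
        return "\n".join(lines)


def transform_error_report(T_est: SimilarityTransform,
                           T_gt: SimilarityTransform) -> ErrorReport:
    """Comparison report between an estimated and a ground-truth transform."""
    w_gt = T_gt.rotvec
    w_est = T_est.rotvec
    def fields(w, s, t):
        return {"omega_x": float(w[0]), "omega_y": float(w[1]),
                "omega_z": float(w[2]),
                "theta_deg": rotation_angle_deg(w),
                "s": float(s), "t_x": float(t[0]), "t_y": float(t[1]),
                "t_z": float(t[2])}
    truths = fields(w_gt, T_gt.s, T_gt.t)
    estimates = fields(w_est, T_est.s, T_est.t)
    errors = {k: estimates[k] - truths[k] for k in truths}
    if np.linalg.norm(w_gt) == 0 or np.linalg.norm(w_est) == 0:
        a = 0.0 if np.allclose(w_gt, w_est) else 180.0
    else:
        a = rotation_vector_angle(w_gt, w_est)
    return ErrorReport(truths, estimates, errors, a)
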