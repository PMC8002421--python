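"""Closed-form absolute orientation between corresponding 3D point sets.

Given paired clouds ``p_i`` (frame 1) and ``q_i`` (frame 2) the similarity
transform ``q ~ s R p + t`` is recovered in closed form:

1. centre both clouds on their centroids, ``p'_i = p_i - pbar``;
2. the optimal rotation is the unit quaternion maximizing
   ``sum_i q'_i . (R(e) p'_i)``, found as the eigenvector of the largest
   eigenvalue of the symmetric 4x4 matrix built from the 3x3
   cross-covariance ``S = sum_i p'_i q'_i^T``;
3. the (asymmetric) scale is ``s = sum_i q'_i . (R p'_i) / sum_i |p'_i|^2``
   and the translation ``t = qbar - s R pbar``.

The quaternion step is also exposed in batched form over many point
triples at once, which is what the robust estimators enumerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateGeometryError, InsufficientPointsError
from .transforms import (SimilarityTransform, canonicalize_quaternion,
                         quaternion_to_matrix)

__all__ = [
    "CorrespondenceSet",
    "quaternion_from_correspondences",
    "scale_and_translation",
    "solve_similarity",
    "batched_triple_quaternions",
    "nondegenerate_triples",
]

# a cloud is degenerate (collinear or coincident) when its centred point
# matrix has rank < 2: second singular value below this fraction of the first
_DEGEN_RTOL = 1e-9


@dataclass
class CorrespondenceSet:
    """N paired 3D map points expressed in two camera/map frames.

    ``p`` holds the points in frame 1, ``q`` the same physical points in
    frame 2; rows are paired by index.  Centroids and centred coordinates
    are exposed as properties.
    """

    p: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float).reshape(-1, 3)
        self.q = np.asarray(self.q, dtype=float).reshape(-1, 3)
        if len(self.p) != len(self.q):
            raise ValueError(
                f"p and q must pair up: {len(self.p)} vs {len(self.q)} points")

    def __len__(self):
        return len(self.p)

    @property
    def p_centroid(self) -> np.ndarray:
        return self.p.mean(axis=0)

    @property
    def q_centroid(self) -> np.ndarray:
        return self.q.mean(axis=0)

    @property
    def p_centered(self) -> np.ndarray:
        return self.p - self.p_centroid

    @property
    def q_centered(self) -> np.ndarray:
        return self.q - self.q_centroid

    def subset(self, idx) -> "CorrespondenceSet":
        return CorrespondenceSet(self.p[list(idx)], self.q[list(idx)])


def _require_n(corr: CorrespondenceSet, n: int = 3):
    if len(corr) < n:
        raise InsufficientPointsError(
            f"need at least {n} correspondences, got {len(corr)}")


def _is_degenerate(centered: np.ndarray) -> bool:
    sv = np.linalg.svd(centered, compute_uv=False)
    return sv[0] == 0 or sv[1] < _DEGEN_RTOL * sv[0]


def _horn_matrix(S: np.ndarray) -> np.ndarray:
    """Symmetric 4x4 matrix whose top eigenvector is the Horn quaternion.

    Accepts a single 3x3 cross-covariance or a stack (..., 3, 3).
    """
    Sxx, Sxy, Sxz = S[..., 0, 0], S[..., 0, 1], S[..., 0, 2]
    Syx, Syy, Syz = S[..., 1, 0], S[..., 1, 1], S[..., 1, 2]
    Szx, Szy, Szz = S[..., 2, 0], S[..., 2, 1], S[..., 2, 2]
    N = np.empty(S.shape[:-2] + (4, 4))
    N[..., 0, 0] = Sxx + Syy + Szz
    N[..., 0, 1] = N[..., 1, 0] = Syz - Szy
    N[..., 0, 2] = N[..., 2, 0] = Szx - Sxz
    N[..., 0, 3] = N[..., 3, 0] = Sxy - Syx
    N[..., 1, 1] = Sxx - Syy - Szz
    N[..., 1, 2] = N[..., 2, 1] = Sxy + Syx
    N[..., 1, 3] = N[..., 3, 1] = Szx + Sxz
    N[..., 2, 2] = -Sxx + Syy - Szz
    N[..., 2, 3] = N[..., 3, 2] = Syz + Szy
    N[..., 3, 3] = -Sxx - Syy + Szz
    return N


def quaternion_from_correspondences(corr: CorrespondenceSet) -> np.ndarray:
    """Optimal rotation as a canonical scalar-first unit quaternion.

    Raises
    ------
    DegenerateGeometryError
        If either cloud is collinear or coincident.
    InsufficientPointsError
        If fewer than 3 correspondences are given.
    """
    _require_n(corr)
    pc, qc = corr.p_centered, corr.q_centered
    if _is_degenerate(pc) or _is_degenerate(qc):
        raise DegenerateGeometryError(
            "collinear or coincident points cannot constrain a rotation")
    S = pc.T @ qc
    w, V = np.linalg.eigh(_horn_matrix(S))
    return canonicalize_quaternion(V[:, -1])


def scale_and_translation(R: np.ndarray, corr: CorrespondenceSet):
    """Asymmetric Horn scale and translation for a given rotation.

    ``s = sum q'.(R p') / sum |p'|^2`` and ``t = qbar - s R pbar``.
    """
    _require_n(corr)
    pc, qc = corr.p_centered, corr.q_centered
    denom = np.einsum("ij,ij->", pc, pc)
    if denom == 0:
        raise DegenerateGeometryError("all p points coincide; scale undefined")
    s = np.einsum("ij,ij->", qc, pc @ np.asarray(R, dtype=float).T) / denom
    if s <= 0:
        raise DegenerateGeometryError(
            f"non-positive scale {s:.3g}: clouds are inconsistent with a "
            "similarity under this rotation")
    t = corr.q_centroid - s * np.asarray(R) @ corr.p_centroid
    return float(s), t


def solve_similarity(corr: CorrespondenceSet) -> SimilarityTransform:
    """Full closed-form similarity fit (rotation, then scale/translation)."""
    e = quaternion_from_correspondences(corr)
    R = quaternion_to_matrix(e)
    s, t = scale_and_translation(R, corr)
    return SimilarityTransform(R, s, t)


# ----------------------------------------------------------------------
# batched machinery used by the robust estimators

def nondegenerate_triples(corr: CorrespondenceSet, triples: np.ndarray):
    """Filter an (m, 3) index array down to triples that are non-collinear
    in both clouds; returns (kept_triples, mask)."""
    triples = np.asarray(triples)
    P = corr.p[triples]            # (m, 3, 3)
    Q = corr.q[triples]
    ok = np.ones(len(triples), dtype=bool)
    for X in (P, Q):
        Xc = X - X.mean(axis=1, keepdims=True)
        sv = np.linalg.svd(Xc, compute_uv=False)   # (m, 3) descending
        ok &= (sv[:, 0] > 0) & (sv[:, 1] >= _DEGEN_RTOL * sv[:, 0])
    return triples[ok], ok


def batched_triple_quaternions(corr: CorrespondenceSet,
                               triples: np.ndarray) -> np.ndarray:
    """Horn quaternions for many 3-point subsets at once.

    Parameters
    ----------
    triples : (m, 3) int array
        Index triples into ``corr``; assumed non-degenerate (see
        :func:`nondegenerate_triples`).

    Returns
    -------
    (m, 4) array of canonical scalar-first unit quaternions.
    """
    triples = np.asarray(triples)
    if triples.size == 0:
        return np.empty((0, 4))
    P = corr.p[triples]
    Q = corr.q[triples]
    Pc = P - P.mean(axis=1, keepdims=True)
    Qc = Q - Q.mean(axis=1, keepdims=True)
    S = np.einsum("mki,mkj->mij", Pc, Qc)
    w, V = np.linalg.eigh(_horn_matrix(S))
    return canonicalize_quaternion(V[..., -1])
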