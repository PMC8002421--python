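"""Robust inter-camera similarity estimation.

Three estimators share one sklearn-style interface (``fit(X, y)`` where
``X`` are the 3D map points in the first camera's frame and ``y`` the same
points in the second camera's frame):

``HornRegistration``
    The closed-form least-squares fit on all N correspondences at once.

``InlierMaximizingRegistration``
    RANSAC-flavoured search: fit a similarity to every 3-point subset,
    count inliers by alignment residual, keep the transform with the most
    inliers (ties: smaller mean inlier residual, then first triple in
    enumeration order).

``QuaternionFilterRegistration``
    The quaternion-filtering improvement: compute the Horn quaternion of
    every C(N,3) triple, reject outlier quaternions component-wise around
    the median (half-width ``sigma_l / d``), average the survivors into a
    representative rotation, then recover scale and translation from all N
    centred correspondences.

All estimators expose ``transform_`` (a
:class:`~endoview.transforms.SimilarityTransform`), ``inlier_mask_``,
``inlier_count_`` and ``residuals_`` after fitting, and compose with
sklearn utilities (``get_params``/``set_params``/``clone``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import DegenerateGeometryError, InsufficientPointsError
from .horn import (CorrespondenceSet, batched_triple_quaternions,
                   nondegenerate_triples, quaternion_from_correspondences,
                   scale_and_translation, solve_similarity)
from .transforms import (SimilarityTransform, canonicalize_quaternion,
                         quaternion_to_matrix)

__all__ = [
    "QuaternionFilterResult",
    "quaternion_filter",
    "enumerate_triples",
    "default_inlier_threshold",
    "HornRegistration",
    "InlierMaximizingRegistration",
    "QuaternionFilterRegistration",
    "estimate_pose_algorithm1",
    "estimate_pose_algorithm2",
]

#: cap on evaluated triples before switching to seeded random sampling;
#: C(30, 3) = 4060, i.e. exhaustive enumeration up to N = 30
MAX_TRIPLES_EXHAUSTIVE = 4060


def default_inlier_threshold(corr: CorrespondenceSet) -> float:
    """0.1 x RMS radius of the centred target cloud (scene units)."""
    qc = corr.q_centered
    return 0.1 * float(np.sqrt(np.mean(np.sum(qc * qc, axis=1))))


def enumerate_triples(n: int, max_triples: int = MAX_TRIPLES_EXHAUSTIVE,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Deterministically ordered 3-subsets of ``range(n)``.

    Exhaustive lexicographic enumeration while C(n,3) <= ``max_triples``;
    beyond that, ``max_triples`` distinct triples sampled with ``rng``.
    """
    total = math.comb(n, 3)
    if total <= max_triples:
        return np.array(list(combinations(range(n), 3)), dtype=int)
    if rng is None:
        rng = np.random.default_rng(0)
    seen = set()
    out = []
    while len(out) < max_triples:
        t = tuple(sorted(rng.choice(n, size=3, replace=False).tolist()))
        if t not in seen:
            seen.add(t)
            out.append(t)
    return np.array(out, dtype=int)


# ----------------------------------------------------------------------
# quaternion filtering

@dataclass
class QuaternionFilterResult:
    """Outcome of median/sigma outlier rejection over candidate quaternions."""

    candidates: np.ndarray      # (n, 4) canonical unit quaternions
    median: np.ndarray          # (4,) component-wise median
    sigma: np.ndarray           # (4,) population std around the mean
    kept_mask: np.ndarray       # (n,) bool
    representative: np.ndarray  # (4,) renormalized mean of the kept set

    @property
    def kept(self) -> np.ndarray:
        return self.candidates[self.kept_mask]

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def quaternion_filter(candidates: np.ndarray, d: float) -> QuaternionFilterResult:
    """Median-centred outlier rejection of rotation quaternions.

    For each component ``l`` the candidates' median ``em_l`` and population
    standard deviation ``sigma_l`` (taken around the component *mean*) are
    computed; a candidate survives only if every component lies within
    ``em_l +/- sigma_l / d``.  Larger ``d`` shrinks the window and keeps
    fewer candidates.  The representative quaternion is the component-wise
    mean of the survivors, renormalized to unit length.

    If the window is so tight that no candidate falls inside it (the
    component-wise median need not be attained by any one candidate), the
    single candidate nearest the median vector is kept.
    """
    if d <= 0:
        raise ValueError(f"removal-range divisor d must be > 0, got {d}")
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if candidates.size == 0:
        raise ValueError("no candidate quaternions to filter")
    candidates = canonicalize_quaternion(candidates)
    median = np.median(candidates, axis=0)
    mean = candidates.mean(axis=0)
    sigma = np.sqrt(np.mean((candidates - mean) ** 2, axis=0))
    half_width = sigma / d
    kept_mask = np.all(np.abs(candidates - median) <= half_width + 1e-12,
                       axis=1)
    if not kept_mask.any():
        nearest = np.argmin(np.linalg.norm(candidates - median, axis=1))
        kept_mask = np.zeros(len(candidates), dtype=bool)
        kept_mask[nearest] = True
    representative = canonicalize_quaternion(candidates[kept_mask].mean(axis=0))
    return QuaternionFilterResult(candidates, median, sigma, kept_mask,
                                  representative)


# ----------------------------------------------------------------------
# estimators

def _residuals(transform: SimilarityTransform, corr: CorrespondenceSet,
               intrinsics=None) -> np.ndarray:
    """Alignment residual per correspondence: 3D distance in scene units,
    or, when second-camera intrinsics are supplied, the 2D reprojection
    distance in pixels (points behind the camera count as infinite)."""
    if intrinsics is None:
        return np.linalg.norm(corr.q - transform.apply(corr.p), axis=1)
    from .geometry import project_points  # local import avoids a cycle
    u_est = project_points(transform.apply(corr.p), intrinsics)
    u_obs = project_points(corr.q, intrinsics)
    res = np.linalg.norm(u_est - u_obs, axis=1)
    return np.where(np.isfinite(res), res, np.inf)


class _BaseRegistration(BaseEstimator):
    """Shared fit plumbing for the similarity-registration estimators."""

    def _check_Xy(self, X, y) -> CorrespondenceSet:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(f"X must be (n_points, 3), got {X.shape}")
        if y.shape != X.shape:
            raise ValueError(f"y must match X's shape, got {y.shape} vs {X.shape}")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite coordinates in input")
        return CorrespondenceSet(X, y)

    def _finalize(self, corr: CorrespondenceSet,
                  transform: SimilarityTransform, threshold: float):
        self.transform_ = transform
        self.rotation_ = transform.R
        self.scale_ = transform.s
        self.translation_ = transform.t
        self.quaternion_ = transform.quaternion
        self.threshold_ = threshold
        self.residuals_ = _residuals(transform, corr,
                                     getattr(self, "intrinsics", None))
        self.inlier_mask_ = self.residuals_ <= threshold
        self.inlier_count_ = int(self.inlier_mask_.sum())
        self.n_features_in_ = 3
        return self

    def _resolve_threshold(self, corr):
        thr = getattr(self, "threshold", None)
        if thr is not None:
            return float(thr)
        K = getattr(self, "intrinsics", None)
        if K is not None:
            # pixel regime: 1% of the image diagonal
            return 0.01 * float(np.hypot(K.width, K.height))
        return default_inlier_threshold(corr)

    def transform(self, X):
        check_is_fitted(self, "transform_")
        return self.transform_.apply(np.asarray(X, dtype=float))

    predict = transform

    def inverse_transform(self, X):
        check_is_fitted(self, "transform_")
        return self.transform_.inverse().apply(np.asarray(X, dtype=float))

    def score(self, X, y):
        """Negative mean squared alignment residual (higher is better)."""
        check_is_fitted(self, "transform_")
        corr = self._check_Xy(X, y)
        return -float(np.mean(_residuals(self.transform_, corr) ** 2))


class HornRegistration(_BaseRegistration):
    """Closed-form Horn fit on all correspondences.

    Parameters
    ----------
    threshold : float or None
        Inlier residual threshold (scene units) used only for the reported
        ``inlier_mask_``; ``None`` means 0.1 x RMS centred-cloud radius.
    """

    def __init__(self, threshold: float | None = None):
        self.threshold = threshold

    def fit(self, X, y):
        corr = self._check_Xy(X, y)
        return self._finalize(corr, solve_similarity(corr),
                              self._resolve_threshold(corr))


class InlierMaximizingRegistration(_BaseRegistration):
    """Triple-search estimator maximizing the inlier count.

    Every (or, above ``max_triples``, a seeded random subset of) 3-point
    combination is fit by Horn's method and scored by the number of
    correspondences whose alignment residual ``|q_i - (s R p_i + t)|``
    falls below ``threshold``.

    Parameters
    ----------
    threshold : float or None
        Inlier threshold in scene units (``None``: 0.1 x RMS centred-cloud
        radius of the target cloud).
    max_triples : int
        Exhaustive enumeration while C(N,3) stays at or below this; seeded
        sampling otherwise.
    random_state : int or None
        Seed for the sampling regime only.
    refit_on_inliers : bool
        If True, refit the returned transform by Horn's method on the
        winning inlier set (off by default: the winning triple's transform
        is returned, as in the original search).
    """

    def __init__(self, threshold: float | None = None,
                 max_triples: int = MAX_TRIPLES_EXHAUSTIVE,
                 random_state: int | None = None,
                 refit_on_inliers: bool = False,
                 intrinsics=None):
        self.threshold = threshold
        self.max_triples = max_triples
        self.random_state = random_state
        self.refit_on_inliers = refit_on_inliers
        self.intrinsics = intrinsics

    def fit(self, X, y):
        corr = self._check_Xy(X, y)
        if len(corr) < 3:
            raise InsufficientPointsError(
                f"need at least 3 correspondences, got {len(corr)}")
        threshold = self._resolve_threshold(corr)
        rng = np.random.default_rng(self.random_state)
        triples = enumerate_triples(len(corr), self.max_triples, rng)
        triples, _ = nondegenerate_triples(corr, triples)
        if len(triples) == 0:
            raise DegenerateGeometryError("all candidate triples are degenerate")
        quats, scales, ts, valid = _triple_transforms(corr, triples)
        if not valid.any():
            raise DegenerateGeometryError("no triple admits a positive scale")
        res = _batched_residuals(corr, quats, scales, ts,
                                 self.intrinsics)      # (m, N)
        res[~valid] = np.inf
        inl = res <= threshold
        counts = inl.sum(axis=1)
        mean_res = np.where(counts > 0,
                            np.where(inl, res, 0.0).sum(axis=1)
                            / np.maximum(counts, 1),
                            np.inf)
        # max inliers, then min mean inlier residual, then first in order
        best = 0
        for m in range(1, len(triples)):
            if counts[m] > counts[best] or (
                    counts[m] == counts[best] and mean_res[m] < mean_res[best]):
                best = m
        T = SimilarityTransform(quaternion_to_matrix(quats[best]),
                                scales[best], ts[best])
        if self.refit_on_inliers and counts[best] >= 3:
            sub = corr.subset(np.flatnonzero(inl[best]))
            try:
                T = solve_similarity(sub)
            except DegenerateGeometryError:
                pass
        self.best_triple_ = tuple(int(i) for i in triples[best])
        self.n_triples_ = len(triples)
        return self._finalize(corr, T, threshold)


class QuaternionFilterRegistration(_BaseRegistration):
    """Quaternion-filtering estimator (robust rotation averaging).

    All C(N,3) triples contribute a candidate Horn quaternion; candidates
    outside the median-centred window of half-width ``sigma_l / d`` in any
    component are discarded; the survivors' renormalized mean gives the
    rotation; scale and translation then come from all N centred
    correspondences via Horn's closed form.

    Parameters
    ----------
    d : float
        Outlier-removal range divisor; larger keeps fewer candidates.
        The evaluation protocol uses 2 and 4.
    """

    def __init__(self, d: float = 2.0, threshold: float | None = None,
                 max_triples: int = MAX_TRIPLES_EXHAUSTIVE,
                 random_state: int | None = None):
        self.d = d
        self.threshold = threshold
        self.max_triples = max_triples
        self.random_state = random_state

    def fit(self, X, y):
        corr = self._check_Xy(X, y)
        if len(corr) < 3:
            raise InsufficientPointsError(
                f"need at least 3 correspondences, got {len(corr)}")
        rng = np.random.default_rng(self.random_state)
        triples = enumerate_triples(len(corr), self.max_triples, rng)
        triples, _ = nondegenerate_triples(corr, triples)
        if len(triples) == 0:
            raise DegenerateGeometryError("all candidate triples are degenerate")
        candidates = batched_triple_quaternions(corr, triples)
        self.filter_result_ = quaternion_filter(candidates, self.d)
        self.n_candidates_ = len(candidates)
        R = quaternion_to_matrix(self.filter_result_.representative)
        s, t = scale_and_translation(R, corr)
        return self._finalize(corr, SimilarityTransform(R, s, t),
                              self._resolve_threshold(corr))


def _triple_transforms(corr: CorrespondenceSet, triples: np.ndarray):
    """Batched per-triple (quaternion, scale, translation); ``valid`` marks
    triples with positive scale."""
    quats = batched_triple_quaternions(corr, triples)
    from scipy.spatial.transform import Rotation
    R = Rotation.from_quat(np.roll(quats, -1, axis=1)).as_matrix()  # (m,3,3)
    P = corr.p[triples]
    Q = corr.q[triples]
    Pc = P - P.mean(axis=1, keepdims=True)
    Qc = Q - Q.mean(axis=1, keepdims=True)
    RP = np.einsum("mij,mkj->mki", R, Pc)
    denom = np.einsum("mki,mki->m", Pc, Pc)
    scales = np.einsum("mki,mki->m", Qc, RP) / denom
    valid = scales > 0
    ts = Q.mean(axis=1) - scales[:, None] * np.einsum(
        "mij,mj->mi", R, P.mean(axis=1))
    return quats, scales, ts, valid


def _batched_residuals(corr, quats, scales, ts, intrinsics=None):
    from scipy.spatial.transform import Rotation
    R = Rotation.from_quat(np.roll(quats, -1, axis=1)).as_matrix()
    mapped = scales[:, None, None] * np.einsum(
        "mij,nj->mni", R, corr.p) + ts[:, None, :]
    if intrinsics is None:
        return np.linalg.norm(mapped - corr.q[None, :, :], axis=2)
    from .geometry import project_points
    m, n = mapped.shape[:2]
    u_est = project_points(mapped.reshape(-1, 3),
                           intrinsics).reshape(m, n, 2)
    u_obs = project_points(corr.q, intrinsics)
    res = np.linalg.norm(u_est - u_obs[None, :, :], axis=2)
    return np.where(np.isfinite(res), res, np.inf)


# ----------------------------------------------------------------------
# functional wrappers

def estimate_pose_algorithm1(corr: CorrespondenceSet,
                             threshold: float | None = None,
                             max_triples: int = MAX_TRIPLES_EXHAUSTIVE,
                             random_state: int | None = None
                             ) -> InlierMaximizingRegistration:
    """Inlier-maximizing triple search on a correspondence set."""
    est = InlierMaximizingRegistration(threshold=threshold,
                                       max_triples=max_triples,
                                       random_state=random_state)
    return est.fit(corr.p, corr.q)


def estimate_pose_algorithm2(corr: CorrespondenceSet, d: float = 2.0,
                             threshold: float | None = None,
                             max_triples: int = MAX_TRIPLES_EXHAUSTIVE,
                             random_state: int | None = None
                             ) -> QuaternionFilterRegistration:
    """Quaternion-filtering estimation on a correspondence set."""
    est = QuaternionFilterRegistration(d=d, threshold=threshold,
                                       max_triples=max_triples,
                                       random_state=random_state)
    return est.fit(corr.p, corr.q)
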