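"""Key frames, descriptor matching and optimal key-frame pair selection.

A vSLAM front end (consumed here as abstract input, never run) produces
key frames: selected video frames whose 2D feature points anchor 3D map
points.  To relate the maps of two cameras, every pair of key frames
(one per camera) is examined; pairs with at least ``min_corr`` map-point
correspondences are fit with the inlier-maximizing search, and the first
pair reaching ``min_inliers`` inliers is declared optimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import InlierMaximizingRegistration
from .exceptions import (DegenerateGeometryError, InsufficientPointsError,
                         UnresolvedClickError)
from .horn import CorrespondenceSet

__all__ = [
    "KeyFrame",
    "hamming_matcher",
    "map_point_correspondences",
    "select_optimal_keyframe_pair",
    "snap_clicks_to_features",
]


@dataclass
class KeyFrame:
    """One key frame: aligned arrays of features, descriptors and map points.

    ``map_point_ids[k] < 0`` marks a feature with no associated map point;
    ``map_points[k]`` is then ignored.
    """

    id: int
    feature_points: np.ndarray            # (M, 2) pixel coordinates
    descriptors: list = field(default_factory=list)   # opaque byte strings
    map_point_ids: np.ndarray = None      # (M,) int, -1 = none
    map_points: np.ndarray = None         # (M, 3) scene coordinates

    def __post_init__(self):
        self.feature_points = np.asarray(self.feature_points,
                                         dtype=float).reshape(-1, 2)
        m = len(self.feature_points)
        if self.map_point_ids is None:
            self.map_point_ids = np.full(m, -1, dtype=int)
        self.map_point_ids = np.asarray(self.map_point_ids, dtype=int)
        if self.map_points is None:
            self.map_points = np.full((m, 3), np.nan)
        self.map_points = np.asarray(self.map_points, dtype=float).reshape(-1, 3)
        if not (len(self.map_point_ids) == m == len(self.map_points)):
            raise ValueError("feature_points, map_point_ids and map_points "
                             "must align by index")
        if self.descriptors and len(self.descriptors) != m:
            raise ValueError("descriptors must align with feature_points")


def _hamming(a: bytes, b: bytes) -> int:
    return sum(bin(x ^ y).count("1") for x, y in zip(a, b))


def hamming_matcher(kf1: KeyFrame, kf2: KeyFrame,
                    max_distance: int | None = None) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour matching of byte descriptors by Hamming
    distance; a fixture-grade matcher for injected descriptors."""
    if not kf1.descriptors or not kf2.descriptors:
        return []
    D = np.array([[_hamming(d1, d2) for d2 in kf2.descriptors]
                  for d1 in kf1.descriptors])
    if max_distance is not None:
        D = np.where(D <= max_distance, D, np.iinfo(int).max)
    best12 = D.argmin(axis=1)
    best21 = D.argmin(axis=0)
    return [(i, int(j)) for i, j in enumerate(best12)
            if best21[j] == i and D[i, j] != np.iinfo(int).max]


def map_point_correspondences(kf1: KeyFrame, kf2: KeyFrame,
                              matches: list[tuple[int, int]]
                              ) -> CorrespondenceSet:
    """Reduce feature matches to the 3D map points both features own."""
    pairs = [(i, j) for i, j in matches
             if kf1.map_point_ids[i] >= 0 and kf2.map_point_ids[j] >= 0]
    if not pairs:
        return CorrespondenceSet(np.empty((0, 3)), np.empty((0, 3)))
    i1, i2 = zip(*pairs)
    return CorrespondenceSet(kf1.map_points[list(i1)], kf2.map_points[list(i2)])


def select_optimal_keyframe_pair(set1: list[KeyFrame], set2: list[KeyFrame],
                                 matcher=hamming_matcher,
                                 min_corr: int = 20, min_inliers: int = 20,
                                 threshold: float | None = None):
    """Scan all n x m key-frame pairs (i-major, j-minor) for the first pair
    with >= ``min_corr`` map-point correspondences whose inlier-maximizing
    fit reaches >= ``min_inliers`` inliers.

    Returns
    -------
    ((kf1, kf2), fitted InlierMaximizingRegistration) or None
        ``None`` signals that no pair qualifies.
    """
    if not set1 or not set2:
        raise ValueError("key-frame sets must be non-empty")
    for kf1 in set1:
        for kf2 in set2:
            corr = map_point_correspondences(kf1, kf2, matcher(kf1, kf2))
            if len(corr) < min_corr:
                continue
            est = InlierMaximizingRegistration(threshold=threshold)
            try:
                est.fit(corr.p, corr.q)
            except (DegenerateGeometryError, InsufficientPointsError):
                continue
            if est.inlier_count_ >= min_inliers:
                return (kf1, kf2), est
    return None


def snap_clicks_to_features(clicks1: np.ndarray, clicks2: np.ndarray,
                            kf1: KeyFrame, kf2: KeyFrame,
                            radius: float = 20.0) -> CorrespondenceSet:
    """Snap manually clicked pixel points to the nearest feature owning a
    map point, pairing the resulting map points across the two frames by
    click order.

    Ties in pixel distance go to the lower feature index.  Clicks with no
    qualifying feature within ``radius`` raise
    :class:`~endoview.exceptions.UnresolvedClickError` listing their
    indices (counted over the concatenation clicks1 + clicks2).
    """
    def snap(clicks, kf, offset):
        clicks = np.asarray(clicks, dtype=float).reshape(-1, 2)
        has_mp = kf.map_point_ids >= 0
        pts, unresolved = [], []
        for c_idx, c in enumerate(clicks):
            dist = np.linalg.norm(kf.feature_points - c, axis=1)
            dist[~has_mp] = np.inf
            k = int(np.argmin(dist))       # argmin takes the lowest index on ties
            if dist[k] > radius:
                unresolved.append(offset + c_idx)
            else:
                pts.append(kf.map_points[k])
        return pts, unresolved

    p, bad1 = snap(clicks1, kf1, 0)
    q, bad2 = snap(clicks2, kf2, len(np.atleast_2d(clicks1)))
    if bad1 or bad2:
        raise UnresolvedClickError(bad1 + bad2, radius)
    if len(p) != len(q):
        raise ValueError("clicks1 and clicks2 must pair up")
    return CorrespondenceSet(np.array(p), np.array(q))
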