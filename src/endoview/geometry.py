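"""Projection geometry for the three expanded-view presentation methods.

A camera's image is projected onto a plane perpendicular to its optical
axis at a chosen distance ``Z`` from the principal point; the projected
image has side lengths ``W' = Z W / fx`` and ``H' = Z H / fy``.  The three
presentation surfaces are then

* the two camera planes themselves (naive overlay / overlap removal, the
  latter clipping one quad at the planes' intersection line),
* a single *bisecting* plane through the intersection line at half the
  inter-plane angle (planar projection),
* a polygonal cylinder tangent to the bisecting plane, approximated by
  rectangular strips (cylindrical projection).

Conventions: right-handed world frame; a camera looks along the +z axis
of its own frame; image x grows right, image y grows down; a plane is
``n . x = h`` with unit normal ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import NoIntersectionError, ValidationError
from .transforms import validate_rotation

__all__ = [
    "CameraIntrinsics",
    "CameraPose",
    "Plane",
    "Line3D",
    "ImageQuad",
    "CylinderSpec",
    "project_points",
    "image_plane_quad",
    "plane_intersection_line",
    "angle_between_planes",
    "bisecting_plane",
    "line_plane_intersection",
    "clip_quad_by_line",
    "cylinder_from_planes",
    "strip_decomposition",
]

_PARALLEL_TOL = 1e-9


@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and image size in pixels."""

    fx: float
    fy: float
    width: int
    height: int
    cx: float | None = None   # principal point; default image centre
    cy: float | None = None

    def __post_init__(self):
        if min(self.fx, self.fy, self.width, self.height) <= 0:
            raise ValidationError("fx, fy, width, height must be > 0")
        if self.cx is None:
            self.cx = self.width / 2.0
        if self.cy is None:
            self.cy = self.height / 2.0

    @property
    def theta_x(self) -> float:
        """Horizontal view angle 2 atan(W / 2 fx), radians."""
        return 2.0 * np.arctan(self.width / (2.0 * self.fx))

    @property
    def theta_y(self) -> float:
        return 2.0 * np.arctan(self.height / (2.0 * self.fy))

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    def to_dict(self) -> dict:
        return {"fx": self.fx, "fy": self.fy, "width": self.width,
                "height": self.height, "cx": self.cx, "cy": self.cy}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(**{k: d[k] for k in ("fx", "fy", "width", "height")},
                   cx=d.get("cx"), cy=d.get("cy"))


@dataclass
class CameraPose:
    """Rigid camera pose: ``X_world = R @ x_camera + C``."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    C: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.R = validate_rotation(self.R)
        self.C = np.asarray(self.C, dtype=float).reshape(3)

    @property
    def optical_axis(self) -> np.ndarray:
        return self.R[:, 2]

    def to_world(self, x):
        return np.asarray(x, dtype=float) @ self.R.T + self.C

    def to_camera(self, X):
        return (np.asarray(X, dtype=float) - self.C) @ self.R


def project_points(points: np.ndarray, K: CameraIntrinsics,
                   pose: CameraPose | None = None) -> np.ndarray:
    """Perspective projection of 3D points into pixel coordinates.

    ``pose`` is the camera's pose in the points' frame (identity: points
    already in camera coordinates).  Points at or behind the principal
    plane (z <= 0) yield NaN pixels.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pose is not None:
        pts = pose.to_camera(pts)
    z = pts[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = K.fx * pts[:, 0] / z + K.cx
        v = K.fy * pts[:, 1] / z + K.cy
    uv = np.stack([u, v], axis=1)
    uv[z <= 0] = np.nan
    return uv


@dataclass
class Plane:
    """Plane ``n . x = h`` with unit normal (inputs normalized)."""

    n: np.ndarray
    h: float

    def __post_init__(self):
        n = np.asarray(self.n, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValidationError("plane normal cannot be zero")
        self.n = n / norm
        self.h = float(self.h) / norm

    @classmethod
    def from_point_normal(cls, point, normal) -> "Plane":
        normal = np.asarray(normal, dtype=float)
        return cls(normal, float(np.dot(normal, point)))

    def signed_distance(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.n - self.h

    def project_point(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X - np.outer(np.atleast_1d(self.signed_distance(X)),
                            self.n).reshape(X.shape)

    def to_dict(self) -> dict:
        return {"n": self.n.tolist(), "h": self.h}


@dataclass
class Line3D:
    """Parametric line ``l(tau) = X0 + tau m`` with unit direction."""

    X0: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        self.X0 = np.asarray(self.X0, dtype=float).reshape(3)
        m = np.asarray(self.m, dtype=float).reshape(3)
        norm = np.linalg.norm(m)
        if norm == 0:
            raise ValidationError("line direction cannot be zero")
        self.m = m / norm

    def point_at(self, tau):
        return self.X0 + np.multiply.outer(np.asarray(tau, dtype=float), self.m)

    def to_dict(self) -> dict:
        return {"X0": self.X0.tolist(), "m": self.m.tolist()}


@dataclass
class ImageQuad:
    """Four 3D vertices of a camera image projected at distance Z,
    ordered top-left, top-right, bottom-right, bottom-left in image terms."""

    vertices: np.ndarray
    plane: Plane

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(4, 3)
        if np.abs(self.plane.signed_distance(self.vertices)).max() > 1e-9:
            raise ValidationError("quad vertices do not lie on its plane")

    @property
    def width(self) -> float:
        return float(np.linalg.norm(self.vertices[1] - self.vertices[0]))

    @property
    def height(self) -> float:
        return float(np.linalg.norm(self.vertices[3] - self.vertices[0]))

    @property
    def center(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


@dataclass
class CylinderSpec:
    """Approximate (polygonal) cylinder for cylindrical projection.

    ``radius * theta_rad = total_width``: the arc spanned by the
    projection angle matches the width of the material to project.
    """

    total_width: float
    theta_deg: float
    radius: float
    axis: Line3D
    tangent_normal: np.ndarray   # unit vector from axis toward the touch line
    n_strips: int = 32

    def __post_init__(self):
        self.tangent_normal = np.asarray(self.tangent_normal,
                                         dtype=float).reshape(3)
        self.tangent_normal /= np.linalg.norm(self.tangent_normal)

    @property
    def theta_rad(self) -> float:
        return np.deg2rad(self.theta_deg)

    def surface_point(self, phi: float, along: float = 0.0) -> np.ndarray:
        """Point on the cylinder at arc angle ``phi`` (0 = touch line) and
        axial offset ``along``."""
        u = np.cross(self.axis.m, self.tangent_normal)
        return (self.axis.X0 + self.radius * (np.cos(phi) * self.tangent_normal
                                              + np.sin(phi) * u)
                + along * self.axis.m)


# ----------------------------------------------------------------------
# operations

def image_plane_quad(K: CameraIntrinsics, pose: CameraPose,
                     Z: float) -> ImageQuad:
    """Quad of the camera image projected at distance Z along the optical
    axis; side lengths ``Z W / fx`` by ``Z H / fy``."""
    if Z <= 0:
        raise ValidationError(f"projection distance Z must be > 0, got {Z}")
    corners_px = np.array([[0.0, 0.0], [K.width, 0.0],
                           [K.width, K.height], [0.0, K.height]])
    cam = np.column_stack([(corners_px[:, 0] - K.cx) / K.fx * Z,
                           (corners_px[:, 1] - K.cy) / K.fy * Z,
                           np.full(4, Z)])
    world = pose.to_world(cam)
    axis = pose.optical_axis
    plane = Plane.from_point_normal(pose.C + Z * axis, axis)
    return ImageQuad(world, plane)


def plane_intersection_line(P1: Plane, P2: Plane) -> Line3D:
    """Closed-form intersection line of two non-parallel planes:
    ``l(tau) = c1 n1 + c2 n2 + tau (n1 x n2)``."""
    c = float(P1.n @ P2.n)
    if abs(c) > 1.0 - _PARALLEL_TOL:
        raise NoIntersectionError("planes are parallel; no intersection line")
    denom = 1.0 - c * c
    c1 = (P1.h - P2.h * c) / denom
    c2 = (P2.h - P1.h * c) / denom
    return Line3D(c1 * P1.n + c2 * P2.n, np.cross(P1.n, P2.n))


def angle_between_planes(P1: Plane, P2: Plane) -> float:
    """Angle between plane normals, degrees in [0, 180]."""
    return float(np.degrees(np.arccos(np.clip(P1.n @ P2.n, -1.0, 1.0))))


def bisecting_plane(P1: Plane, P2: Plane) -> Plane:
    """Plane through the intersection line at half the inter-plane angle.

    Of the two bisectors the one whose normal aligns with ``n1 + n2``
    (facing the cameras) is returned.  Coincident planes bisect to
    themselves.
    """
    c = float(P1.n @ P2.n)
    if abs(c) > 1.0 - _PARALLEL_TOL:
        if c > 0 and abs(P1.h - P2.h) < 1e-9:
            return Plane(P1.n.copy(), P1.h)
        raise NoIntersectionError("parallel distinct planes have no bisector "
                                  "through an intersection line")
    line = plane_intersection_line(P1, P2)
    nb = P1.n + P2.n
    return Plane.from_point_normal(line.X0, nb / np.linalg.norm(nb))


def line_plane_intersection(line: Line3D, plane: Plane) -> np.ndarray:
    """``X = X0 + (h - n.X0)/(n.m) m``; errors when the line is parallel
    to the plane."""
    nm = float(plane.n @ line.m)
    if abs(nm) <= 1e-12:
        raise NoIntersectionError("line is parallel to the plane")
    return line.X0 + (plane.h - plane.n @ line.X0) / nm * line.m


def clip_quad_by_line(quad, line: Line3D, keep_point: np.ndarray,
                      tol: float = 1e-12) -> np.ndarray:
    """Clip a convex planar polygon by a line, keeping ``keep_point``'s side.

    The line is first projected into the polygon's plane.  Returns the
    vertex array of the clipped polygon: unchanged (the line misses the
    polygon entirely), a smaller triangle/trapezoid (4 vertices) or a
    pentagon (5 vertices) -- the shape taxonomy of overlap-area removal.
    """
    if isinstance(quad, ImageQuad):
        verts, plane = quad.vertices, quad.plane
    else:
        verts = np.asarray(quad, dtype=float).reshape(-1, 3)
        n = np.cross(verts[1] - verts[0], verts[2] - verts[0])
        plane = Plane.from_point_normal(verts[0], n)
    # project the line into the polygon's plane
    m_in = line.m - (line.m @ plane.n) * plane.n
    if np.linalg.norm(m_in) <= tol:
        raise NoIntersectionError("line is perpendicular to the quad plane")
    X0_in = plane.project_point(line.X0)
    # in-plane normal to the line defines the clipping half-plane
    w = np.cross(plane.n, m_in / np.linalg.norm(m_in))
    side = float((np.asarray(keep_point, dtype=float) - X0_in) @ w)
    if abs(side) <= tol:
        raise ValidationError("keep_point lies on the clipping line")
    w = w * np.sign(side)

    d = (verts - X0_in) @ w
    if np.all(d >= -tol):
        return verts.copy()
    out = []
    k = len(verts)
    for i in range(k):
        a, b = verts[i], verts[(i + 1) % k]
        da, db = d[i], d[(i + 1) % k]
        if da >= -tol:
            out.append(a)
        if (da > tol and db < -tol) or (da < -tol and db > tol):
            out.append(a + (da / (da - db)) * (b - a))
    return np.array(out).reshape(-1, 3)


def cylinder_from_planes(bisect: Plane, intersection: Line3D,
                         total_width: float, theta_deg: float = 120.0,
                         n_strips: int = 32,
                         touch_point: np.ndarray | None = None) -> CylinderSpec:
    """Approximate cylinder tangent to the bisecting plane.

    ``radius = W_T * 360 / (2 pi theta)`` so that the arc subtended by
    ``theta`` has exactly the length of the material to project.  The axis
    runs parallel to the planes' intersection line at distance ``radius``
    behind the bisecting plane, touching it along the midline through
    ``touch_point`` (default: the intersection line's reference point
    projected onto the plane).
    """
    if total_width <= 0:
        raise ValidationError("total width must be > 0")
    if not 0 < theta_deg <= 360:
        raise ValidationError("theta must lie in (0, 360] degrees")
    radius = total_width * 360.0 / (2.0 * np.pi * theta_deg)
    if touch_point is None:
        touch_point = intersection.X0
    touch_point = bisect.project_point(np.asarray(touch_point, dtype=float))
    axis_point = touch_point - radius * bisect.n
    return CylinderSpec(total_width, theta_deg, radius,
                        Line3D(axis_point, intersection.m), bisect.n,
                        n_strips)


def strip_decomposition(cyl: CylinderSpec, height: float,
                        n_strips: int | None = None,
                        center_along: float = 0.0) -> list[np.ndarray]:
    """Planar strip quads whose chords lie on the polygonal cylinder.

    The projection arc (angle ``theta``, centred on the touch line) is cut
    into ``n_strips`` equal sectors; each strip is the planar quad spanned
    by the two chord endpoints extruded ``height`` along the axis.  Strip
    arc widths partition the total width exactly, and the chords' maximum
    deviation from the true cylinder (the sagitta ``r (1 - cos(dphi/2))``)
    shrinks monotonically as ``n_strips`` grows.
    """
    if n_strips is None:
        n_strips = cyl.n_strips
    if n_strips < 1:
        raise ValidationError("need at least one strip")
    th = cyl.theta_rad
    phis = np.linspace(-th / 2.0, th / 2.0, n_strips + 1)
    lo = center_along - height / 2.0
    hi = center_along + height / 2.0
    quads = []
    for a, b in zip(phis[:-1], phis[1:]):
        quads.append(np.array([
            cyl.surface_point(a, lo), cyl.surface_point(b, lo),
            cyl.surface_point(b, hi), cyl.surface_point(a, hi),
        ]))
    return quads
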