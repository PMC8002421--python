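"""Offline construction of the expanded 2D view.

The renderer is a deterministic software replacement for an OpenGL
texture-mapping pipeline: every canvas pixel is back-projected from a
virtual viewpoint onto the presentation surface (the camera planes, the
bisecting plane, clipped quads, or cylinder strips), the surface point is
reprojected into each source camera, and the source image is sampled
there (bilinear by default; nearest-neighbour for exact tests).

Pixels no camera covers stay blank (0) and are distinguished by a
provenance mask: bit 1 = camera 1, bit 2 = camera 2 (3 = both).  Overlap
removal never produces a "both" pixel by construction: the cropped
camera only writes where the canvas is still blank, so seam pixels belong
to the uncropped camera.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.draw import polygon as raster_polygon

from .exceptions import DegenerateViewError, NoIntersectionError
from .geometry import (CameraIntrinsics, CameraPose, ImageQuad, Line3D, Plane,
                       bisecting_plane, clip_quad_by_line, image_plane_quad,
                       plane_intersection_line, strip_decomposition,
                       cylinder_from_planes)

__all__ = ["ExpandedView", "render_expanded_view", "footprint_polygon",
           "default_viewpoint", "fit_output_camera"]

METHODS = ("naive_overlay", "planar", "overlap_removal", "cylindrical")

MASK_BLANK, MASK_CAM1, MASK_CAM2, MASK_BOTH = 0, 1, 2, 3


@dataclass
class ExpandedView:
    """Rendered expanded view plus everything needed to reproduce it."""

    canvas: np.ndarray          # (H, W) or (H, W, 3) float in [0, 1]
    mask: np.ndarray            # (H, W) uint8 provenance bits
    method: str
    viewpoint: CameraPose
    K_out: CameraIntrinsics
    footprints: dict            # camera index -> list of (k, 2) canvas polygons


def default_viewpoint(pose1: CameraPose, pose2: CameraPose) -> CameraPose:
    """Midpoint of the two camera centres, looking along the mean optical
    axis (x axis re-orthogonalized from the mean camera x)."""
    z = pose1.optical_axis + pose2.optical_axis
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise DegenerateViewError("cameras look in opposite directions; "
                                  "supply a viewpoint explicitly")
    z = z / nz
    x0 = pose1.R[:, 0] + pose2.R[:, 0]
    x = x0 - (x0 @ z) * z
    if np.linalg.norm(x) < 1e-12:
        x = np.cross([0.0, 1.0, 0.0], z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return CameraPose(np.column_stack([x, y, z]),
                      0.5 * (pose1.C + pose2.C))


def fit_output_camera(vertices: np.ndarray, viewpoint: CameraPose,
                      out_size: tuple, margin: float = 0.02
                      ) -> CameraIntrinsics:
    """Virtual-camera intrinsics framing all surface vertices on the canvas."""
    H, W = out_size
    cam = viewpoint.to_camera(np.asarray(vertices, dtype=float))
    if np.any(cam[:, 2] <= 0):
        raise DegenerateViewError("presentation surface extends behind the "
                                  "virtual viewpoint")
    nx = cam[:, 0] / cam[:, 2]
    ny = cam[:, 1] / cam[:, 2]
    def span(lo, hi, size):
        pad = margin * (hi - lo + 1e-12)
        lo, hi = lo - pad, hi + pad
        f = size / (hi - lo)
        return f, -lo * f
    fx, cx = span(nx.min(), nx.max(), W)
    fy, cy = span(ny.min(), ny.max(), H)
    return CameraIntrinsics(fx, fy, W, H, cx, cy)


def footprint_polygon(vertices: np.ndarray, viewpoint: CameraPose,
                      K_out: CameraIntrinsics) -> np.ndarray:
    """Exact canvas image of a surface polygon under the viewpoint mapping."""
    cam = viewpoint.to_camera(np.asarray(vertices, dtype=float).reshape(-1, 3))
    if np.any(cam[:, 2] <= 0):
        raise DegenerateViewError("polygon extends behind the viewpoint")
    u = K_out.fx * cam[:, 0] / cam[:, 2] + K_out.cx
    v = K_out.fy * cam[:, 1] / cam[:, 2] + K_out.cy
    return np.stack([u, v], axis=1)


def _piece_plane(vertices: np.ndarray) -> Plane:
    v = np.asarray(vertices, dtype=float)
    n = np.cross(v[1] - v[0], v[2] - v[0])
    return Plane.from_point_normal(v[0], n)


def _project_quad_to_plane(quad: ImageQuad, center: np.ndarray,
                           plane: Plane) -> np.ndarray:
    """Project quad corners from the camera centre onto a plane (the
    planar-presentation mapping of the image outline)."""
    from .geometry import line_plane_intersection
    out = []
    for v in quad.vertices:
        out.append(line_plane_intersection(Line3D(center, v - center), plane))
    return np.array(out)


def _sample(img: np.ndarray, u: np.ndarray, v: np.ndarray,
            order: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample image at continuous pixel coords (u right, v down); pixel
    centres sit at half-integers.  Returns (values, validity)."""
    H, W = img.shape[:2]
    rows, cols = v - 0.5, u - 0.5
    inside = (u >= 0) & (u <= W) & (v >= 0) & (v <= H)
    coords = np.vstack([np.clip(rows, 0, H - 1), np.clip(cols, 0, W - 1)])
    if img.ndim == 2:
        vals = map_coordinates(img, coords, order=order, mode="nearest")
    else:
        vals = np.stack([map_coordinates(img[..., ch], coords, order=order,
                                         mode="nearest")
                         for ch in range(img.shape[2])], axis=-1)
    return vals, inside


def render_expanded_view(img1: np.ndarray, img2: np.ndarray,
                         pose1: CameraPose, pose2: CameraPose,
                         K1: CameraIntrinsics, K2: CameraIntrinsics,
                         method: str = "overlap_removal", Z: float = 1.0,
                         viewpoint: CameraPose | None = None,
                         out_size: tuple = (480, 640),
                         K_out: CameraIntrinsics | None = None,
                         sampling: str = "bilinear",
                         crop_side: int = 2,
                         theta_cylinder: float = 120.0,
                         n_strips: int = 32,
                         cameras: tuple = (1, 2)) -> ExpandedView:
    """Render the expanded view of two posed images.

    Parameters
    ----------
    method : one of "naive_overlay", "planar", "overlap_removal", "cylindrical"
    Z : float
        Projection-plane distance from each camera's principal point.
    viewpoint, K_out :
        Virtual camera; defaults to the mid-pose and intrinsics fit to the
        surface (pass both to compare renders on identical canvases).
    crop_side : 1 or 2
        Which camera's quad is clipped in overlap removal.
    cameras : subset of (1, 2)
        Restrict which sources are drawn (the surface geometry still uses
        both poses).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    order = {"bilinear": 1, "nearest": 0}[sampling]
    imgs = {1: np.asarray(img1, dtype=float), 2: np.asarray(img2, dtype=float)}
    poses = {1: pose1, 2: pose2}
    Ks = {1: K1, 2: K2}
    quads = {i: image_plane_quad(Ks[i], poses[i], Z) for i in (1, 2)}

    # pieces: (surface polygon vertices, owner camera, exclusive_write)
    pieces: list[tuple[np.ndarray, int, bool]] = []
    if method == "naive_overlay":
        pieces = [(quads[1].vertices, 1, False), (quads[2].vertices, 2, False)]
    elif method == "overlap_removal":
        line = plane_intersection_line(quads[1].plane, quads[2].plane)
        keep_i, whole_i = (crop_side, 3 - crop_side)
        other_center_on_plane = quads[keep_i].plane.project_point(
            quads[whole_i].center)
        dists = np.linalg.norm(quads[keep_i].vertices
                               - other_center_on_plane, axis=1)
        keep_point = quads[keep_i].vertices[int(np.argmax(dists))]
        clipped = clip_quad_by_line(quads[keep_i], line, keep_point)
        if whole_i == 1:
            pieces = [(quads[1].vertices, 1, False), (clipped, 2, True)]
        else:
            pieces = [(quads[2].vertices, 2, False), (clipped, 1, True)]
    elif method == "planar":
        pb = bisecting_plane(quads[1].plane, quads[2].plane)
        for i in (1, 2):
            poly = _project_quad_to_plane(quads[i], poses[i].C, pb)
            pieces.append((poly, i, False))
    else:  # cylindrical
        pb = bisecting_plane(quads[1].plane, quads[2].plane)
        line = plane_intersection_line(quads[1].plane, quads[2].plane)
        polys = [_project_quad_to_plane(quads[i], poses[i].C, pb)
                 for i in (1, 2)]
        allv = np.vstack(polys)
        u_dir = np.cross(line.m, pb.n)
        along = allv @ line.m
        across = allv @ u_dir
        total_width = float(across.max() - across.min())
        height = float(along.max() - along.min())
        touch = allv.mean(axis=0)
        cyl = cylinder_from_planes(pb, line, total_width, theta_cylinder,
                                   n_strips, touch_point=touch)
        center_along = float(np.mean(along) - cyl.axis.X0 @ line.m)
        strips = strip_decomposition(cyl, height, n_strips, center_along)
        for strip in strips:
            for i in (1, 2):
                pieces.append((strip, i, False))

    if viewpoint is None:
        viewpoint = default_viewpoint(pose1, pose2)
    if K_out is None:
        K_out = fit_output_camera(np.vstack([v for v, _, _ in pieces]),
                                  viewpoint, out_size)
    H, W = K_out.height, K_out.width
    canvas = np.zeros((H, W) + (() if imgs[1].ndim == 2 else (3,)))
    mask = np.zeros((H, W), dtype=np.uint8)
    footprints: dict[int, list] = {1: [], 2: []}

    Rout, Cout = viewpoint.R, viewpoint.C
    for verts, cam_i, exclusive in pieces:
        poly2d = footprint_polygon(verts, viewpoint, K_out)
        footprints[cam_i].append(poly2d)
        if cam_i not in cameras:
            continue
        rr, cc = raster_polygon(poly2d[:, 1] - 0.5, poly2d[:, 0] - 0.5,
                                shape=(H, W))
        if len(rr) == 0:
            continue
        plane = _piece_plane(verts)
        # back-project canvas pixels onto the piece plane
        d_cam = np.stack([(cc + 0.5 - K_out.cx) / K_out.fx,
                          (rr + 0.5 - K_out.cy) / K_out.fy,
                          np.ones_like(rr, dtype=float)], axis=-1)
        d = d_cam @ Rout.T
        nd = d @ plane.n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (plane.h - plane.n @ Cout) / nd
        valid = np.isfinite(t) & (t > 0)
        X = Cout + t[:, None] * d
        # reproject into the source camera and sample
        src = poses[cam_i]
        xc = (X - src.C) @ src.R
        valid &= xc[:, 2] > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            u = Ks[cam_i].fx * xc[:, 0] / xc[:, 2] + Ks[cam_i].cx
            v = Ks[cam_i].fy * xc[:, 1] / xc[:, 2] + Ks[cam_i].cy
        vals, inside = _sample(imgs[cam_i], u, v, order)
        valid &= inside
        if exclusive:
            valid &= mask[rr, cc] == MASK_BLANK
        rr, cc, vals = rr[valid], cc[valid], vals[valid]
        canvas[rr, cc] = vals
        mask[rr, cc] |= (MASK_CAM1 if cam_i == 1 else MASK_CAM2)
    return ExpandedView(canvas, mask, method, viewpoint, K_out, footprints)
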