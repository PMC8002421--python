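import numpy as np
import pytest

from endoview.exceptions import NoIntersectionError, ValidationError
from endoview.geometry import (CameraIntrinsics, CameraPose, Line3D, Plane,
                               angle_between_planes, bisecting_plane,
                               clip_quad_by_line, cylinder_from_planes,
                               image_plane_quad, line_plane_intersection,
                               plane_intersection_line, project_points,
                               strip_decomposition)


def _random_plane(rng):
    return Plane(rng.normal(size=3), rng.uniform(-3, 3))


class TestImagePlaneQuad:
    def test_projected_size_formula(self):
        K = CameraIntrinsics(500.0, 400.0, 640, 480)
        quad = image_plane_quad(K, CameraPose(), Z=1000.0)
        assert quad.width == pytest.approx(1000.0 * 640 / 500.0)   # 1280
        assert quad.height == pytest.approx(1000.0 * 480 / 400.0)
        # view-angle identity W' = 2 Z tan(theta_x / 2)
        assert quad.width == pytest.approx(
            2 * 1000.0 * np.tan(K.theta_x / 2))

    def test_z_equal_focal_gives_pixel_size(self):
        K = CameraIntrinsics(500.0, 500.0, 640, 480)
        quad = image_plane_quad(K, CameraPose(), Z=500.0)
        assert quad.width == pytest.approx(640.0)
        assert quad.height == pytest.approx(480.0)

    def test_linear_in_z_and_perpendicular_to_axis(self):
        K = CameraIntrinsics(300.0, 300.0, 320, 240)
        pose = CameraPose()
        q1 = image_plane_quad(K, pose, 1.0)
        q2 = image_plane_quad(K, pose, 2.0)
        assert q2.width == pytest.approx(2 * q1.width)
        assert np.allclose(q1.plane.n, pose.optical_axis)
        with pytest.raises(ValidationError):
            image_plane_quad(K, pose, 0.0)


class TestPlaneIntersections:
    def test_coordinate_planes_intersect_along_x_axis(self):
        line = plane_intersection_line(Plane([0, 0, 1], 0.0),
                                       Plane([0, 1, 0], 0.0))
        assert np.allclose(line.X0, 0.0, atol=1e-12)
        assert np.allclose(np.abs(line.m), [1, 0, 0])

    def test_parallel_planes_raise(self):
        with pytest.raises(NoIntersectionError):
            plane_intersection_line(Plane([0, 0, 1], 0.0),
                                    Plane([0, 0, 1], 1.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_line_satisfies_both_plane_equations(self, seed):
        rng = np.random.default_rng(seed)
        P1, P2 = _random_plane(rng), _random_plane(rng)
        line = plane_intersection_line(P1, P2)
        for tau in (-3.0, 0.0, 5.0):
            X = line.point_at(tau)
            assert abs(P1.n @ X - P1.h) < 1e-9
            assert abs(P2.n @ X - P2.h) < 1e-9


class TestAngles:
    def test_orthogonal_and_identical(self):
        assert angle_between_planes(Plane([0, 0, 1], 0),
                                    Plane([1, 0, 0], 0)) == pytest.approx(90.0)
        assert angle_between_planes(Plane([0, 0, 1], 0),
                                    Plane([0, 0, 1], 2)) == pytest.approx(0.0)

    def test_constructed_sixty_degrees(self):
        n2 = [np.sin(np.pi / 3), 0.0, np.cos(np.pi / 3)]
        assert angle_between_planes(Plane([0, 0, 1], 0),
                                    Plane(n2, 0)) == pytest.approx(60.0)


class TestBisectingPlane:
    def test_symmetric_case(self):
        B = bisecting_plane(Plane([0, 0, 1], 0), Plane([1, 0, 0], 0))
        assert np.allclose(B.n, np.array([1, 0, 1]) / np.sqrt(2))
        assert B.h == pytest.approx(0.0, abs=1e-12)

    def test_coincident_planes_bisect_to_themselves(self):
        P = Plane([0, 0, 1], 2.0)
        B = bisecting_plane(P, Plane([0, 0, 1], 2.0))
        assert np.allclose(B.n, P.n)
        assert B.h == pytest.approx(P.h)

    @pytest.mark.parametrize("seed", range(10))
    def test_halves_the_angle_and_contains_the_line(self, seed):
        rng = np.random.default_rng(100 + seed)
        P1, P2 = _random_plane(rng), _random_plane(rng)
        theta = angle_between_planes(P1, P2)
        B = bisecting_plane(P1, P2)
        assert angle_between_planes(B, P1) == pytest.approx(theta / 2,
                                                            abs=1e-9)
        assert angle_between_planes(B, P2) == pytest.approx(theta / 2,
                                                            abs=1e-9)
        line = plane_intersection_line(P1, P2)
        assert np.abs(B.signed_distance(line.point_at(
            np.array([-2.0, 0.0, 3.0])))).max() < 1e-9
        assert B.n @ (P1.n + P2.n) > 0


class TestLinePlaneIntersection:
    def test_axis_line_hits_plane(self):
        X = line_plane_intersection(Line3D([0, 0, 0], [0, 0, 1]),
                                    Plane([0, 0, 1], 5.0))
        assert np.allclose(X, [0, 0, 5])

    def test_parallel_line_raises(self):
        with pytest.raises(NoIntersectionError):
            line_plane_intersection(Line3D([0, 0, 1], [1, 0, 0]),
                                    Plane([0, 0, 1], 5.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_substitution(self, seed):
        rng = np.random.default_rng(seed)
        plane = _random_plane(rng)
        line = Line3D(rng.normal(size=3), rng.normal(size=3))
        X = line_plane_intersection(line, plane)
        assert abs(plane.n @ X - plane.h) < 1e-9
        # X on the line: (X - X0) parallel to m
        assert np.linalg.norm(np.cross(X - line.X0, line.m)) < 1e-8


def _unit_quad():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
    from endoview.geometry import ImageQuad
    return ImageQuad(verts, Plane([0, 0, 1], 0.0))


class TestClipQuadByLine:
    def test_missing_line_leaves_quad_unchanged(self):
        quad = _unit_quad()
        line = Line3D([5.0, 0, 0], [0, 1, 0])
        out = clip_quad_by_line(quad, line, keep_point=[0.5, 0.5, 0.0])
        assert np.allclose(out, quad.vertices)

    def test_edge_parallel_line_gives_trapezoid(self):
        quad = _unit_quad()
        line = Line3D([0.6, 0.0, 0], [0, 1, 0])
        out = clip_quad_by_line(quad, line, keep_point=[0.1, 0.5, 0.0])
        assert len(out) == 4
        assert out[:, 0].max() == pytest.approx(0.6)

    def test_corner_cut_gives_pentagon(self):
        quad = _unit_quad()
        # the line x + y = 0.8 crosses two adjacent sides; keeping the side
        # away from the origin corner leaves a pentagon
        line = Line3D([0.8, 0.0, 0], [-1, 1, 0])
        out = clip_quad_by_line(quad, line, keep_point=[0.9, 0.9, 0.0])
        assert len(out) == 5

    def test_keeping_only_a_corner_gives_triangle(self):
        quad = _unit_quad()
        line = Line3D([0.8, 0.0, 0], [-1, 1, 0])
        out = clip_quad_by_line(quad, line, keep_point=[0.05, 0.05, 0.0])
        assert len(out) == 3

    def test_shape_taxonomy_over_line_grid(self):
        """Any single-line clip of a convex quad is a 3/4/5-gon (or the
        quad untouched): the trapezoid/pentagon taxonomy, never more."""
        quad = _unit_quad()
        areas = _polygon_area(quad.vertices)
        for angle in np.linspace(0, np.pi, 13):
            for offset in np.linspace(-0.5, 1.5, 17):
                m = np.array([np.cos(angle), np.sin(angle), 0.0])
                X0 = np.array([offset, 0.3, 0.0])
                for keep in ([0.01, 0.01, 0.0], [0.99, 0.99, 0.0]):
                    try:
                        out = clip_quad_by_line(quad, Line3D(X0, m), keep)
                    except ValidationError:
                        continue   # keep point fell on the line
                    assert len(out) in (3, 4, 5)
                    assert _polygon_area(out) <= areas + 1e-9


def _polygon_area(verts):
    v = np.asarray(verts)[:, :2]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestCylinder:
    def _setup(self):
        B = Plane([0, 0, 1], 1.0)
        line = Line3D([0, 0, 1.0], [0, 1, 0])
        return B, line

    def test_radius_formula(self):
        B, line = self._setup()
        cyl = cylinder_from_planes(B, line, total_width=10.0, theta_deg=360.0)
        assert cyl.radius == pytest.approx(10.0 / (2 * np.pi))
        cyl = cylinder_from_planes(B, line, total_width=10.0, theta_deg=180.0)
        assert cyl.radius == pytest.approx(10.0 / np.pi)

    def test_arc_length_identity_and_tangency(self):
        B, line = self._setup()
        cyl = cylinder_from_planes(B, line, total_width=7.0, theta_deg=120.0)
        assert cyl.radius * cyl.theta_rad == pytest.approx(7.0, abs=1e-9)
        # axis sits radius behind the plane; the touch line lies on it
        assert B.signed_distance(cyl.axis.X0) == pytest.approx(-cyl.radius)
        assert abs(B.signed_distance(cyl.surface_point(0.0))) < 1e-9

    def test_strip_partition_and_sagitta(self):
        B, line = self._setup()
        cyl = cylinder_from_planes(B, line, total_width=6.0, theta_deg=120.0)
        prev_sagitta = np.inf
        for n in (1, 2, 4, 8, 16):
            quads = strip_decomposition(cyl, height=2.0, n_strips=n)
            assert len(quads) == n
            # chord endpoints on the cylinder
            for quad in quads:
                r = np.linalg.norm(
                    (quad - cyl.axis.X0)
                    - np.outer((quad - cyl.axis.X0) @ cyl.axis.m, cyl.axis.m),
                    axis=1)
                assert np.allclose(r, cyl.radius, atol=1e-9)
            # arc widths partition the total width
            dphi = cyl.theta_rad / n
            assert n * cyl.radius * dphi == pytest.approx(6.0)
            sagitta = cyl.radius * (1 - np.cos(dphi / 2))
            mid = 0.5 * (quads[0][0] + quads[0][1])
            d_axis = np.linalg.norm(
                (mid - cyl.axis.X0)
                - ((mid - cyl.axis.X0) @ cyl.axis.m) * cyl.axis.m)
            assert cyl.radius - d_axis == pytest.approx(sagitta, abs=1e-9)
            assert sagitta < prev_sagitta or n == 1
            prev_sagitta = sagitta


def test_project_points_pinhole():
    K = CameraIntrinsics(100.0, 100.0, 200, 100)
    uv = project_points([[0.0, 0.0, 2.0], [1.0, 0.5, 2.0]], K)
    assert np.allclose(uv[0], [100.0, 50.0])
    assert np.allclose(uv[1], [150.0, 75.0])
    behind = project_points([[0.0, 0.0, -1.0]], K)
    assert np.isnan(behind).all()
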