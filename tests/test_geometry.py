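import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgbdgaze.errors import DegenerateGeometryError, InvalidInputError
from rgbdgaze.geometry import (
    CameraModel,
    Plane,
    Ray,
    Sphere,
    angular_error,
    backproject,
    plane_from_points,
    project,
    ray_plane_intersection,
    ray_sphere_hit,
    unit,
    vec3,
)

from conftest import random_point

finite3 = st.tuples(*[st.floats(-1e3, 1e3)] * 3)


class TestPlaneFromPoints:
    def test_board_plane(self):
        plane = plane_from_points((0, 0, -398.3), (1, 0, -398.3), (0, 1, -398.3))
        assert np.allclose(plane.normal, [0, 0, 1])
        assert plane.signed_distance((5, -3, -398.3)) == pytest.approx(0, abs=1e-9)

    def test_canonical_plane(self):
        plane = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert plane.signed_distance((9, 9, 0)) == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize(
        "pts",
        [
            (((0, 0, 0), (1, 1, 1), (2, 2, 2))),  # collinear
            (((1, 2, 3), (1, 2, 3), (0, 0, 1))),  # coincident
        ],
    )
    def test_degenerate(self, pts):
        with pytest.raises(DegenerateGeometryError):
            plane_from_points(*pts)

    def test_contains_all_three_points(self, rng):
        for _ in range(50):
            pts = [random_point(rng) for _ in range(3)]
            try:
                plane = plane_from_points(*pts)
            except DegenerateGeometryError:
                continue
            for p in pts:
                assert abs(plane.signed_distance(p)) < 1e-8

    def test_normal_sign_is_order_independent(self, rng):
        p1, p2, p3 = (random_point(rng) for _ in range(3))
        a = plane_from_points(p1, p2, p3)
        b = plane_from_points(p3, p1, p2)
        assert np.allclose(a.normal, b.normal)


class TestRayPlaneIntersection:
    board = Plane(point=(0, 0, -398.3), normal=(0, 0, 1))

    def test_straight_ahead(self):
        ray = Ray(origin=(0, 0, 0), direction=(0, 0, -1))
        hit = ray_plane_intersection(ray, self.board)
        assert np.allclose(hit, [0, 0, -398.3])

    def test_parallel_is_no_hit(self):
        ray = Ray(origin=(0, 0, 0), direction=(1, 0, 0))
        assert ray_plane_intersection(ray, self.board) is None

    def test_behind_origin_is_no_hit(self):
        ray = Ray(origin=(0, 0, 0), direction=(0, 0, 1))
        assert ray_plane_intersection(ray, self.board) is None

    def test_oblique_45_degrees(self):
        ray = Ray(origin=(0, 0, 0), direction=(1, 0, -1))
        hit = ray_plane_intersection(ray, Plane(point=(0, 0, -2), normal=(0, 0, 1)))
        assert np.allclose(hit, [2, 0, -2])

    def test_residual_on_plane(self, rng):
        for _ in range(100):
            plane = Plane(point=random_point(rng), normal=unit(rng.standard_normal(3)))
            ray = Ray(origin=random_point(rng), direction=unit(rng.standard_normal(3)))
            hit = ray_plane_intersection(ray, plane)
            if hit is not None:
                assert abs(plane.signed_distance(hit)) < 1e-9 * max(
                    1.0, np.linalg.norm(hit)
                )


class TestRaySphereHit:
    def test_axial_hit(self):
        hit, point = ray_sphere_hit(
            Ray(origin=(0, 0, 0), direction=(0, 0, -1)),
            Sphere(center=(0, 0, -100), radius=12),
        )
        assert hit and np.allclose(point, [0, 0, -88])

    def test_offset_miss(self):
        hit, point = ray_sphere_hit(
            Ray(origin=(0, 0, 0), direction=(0, 0, -1)),
            Sphere(center=(13, 0, -100), radius=12),
        )
        assert not hit and point is None

    def test_tangent_counts_as_hit(self):
        hit, point = ray_sphere_hit(
            Ray(origin=(0, 0, 0), direction=(0, 0, -1)),
            Sphere(center=(12, 0, -100), radius=12),
        )
        assert hit
        assert np.allclose(point, [0, 0, -100])

    def test_sphere_behind_origin_is_miss(self):
        hit, _ = ray_sphere_hit(
            Ray(origin=(0, 0, 0), direction=(0, 0, -1)),
            Sphere(center=(0, 0, 50), radius=12),
        )
        assert not hit

    def test_origin_inside_sphere_hits_forward(self):
        hit, point = ray_sphere_hit(
            Ray(origin=(0, 0, 0), direction=(0, 0, -1)),
            Sphere(center=(0, 0, 0), radius=5),
        )
        assert hit and np.allclose(point, [0, 0, -5])

    def test_against_grid_sampling_oracle(self, rng):
        # brute force: sample t finely; closest approach under the radius
        # (with a grid-resolution guard band) must agree with the solver
        ts = np.linspace(1e-3, 400.0, 20001)
        for _ in range(1000):
            ray = Ray(origin=random_point(rng, 50), direction=unit(rng.standard_normal(3)))
            sphere = Sphere(center=random_point(rng, 100), radius=rng.uniform(5, 30))
            pts = ray.origin[None, :] + ts[:, None] * ray.direction[None, :]
            dmin = np.min(np.linalg.norm(pts - sphere.center, axis=1))
            hit, _ = ray_sphere_hit(ray, sphere)
            if dmin < sphere.radius - 0.05:
                assert hit
            elif dmin > sphere.radius + 0.05:
                assert not hit


class TestAngularError:
    @pytest.mark.parametrize(
        "v1,v2,expected",
        [
            ((0, 0, 1), (0, 0, 1), 0.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((0, 0, 1), (0, 0, -1), 180.0),
        ],
    )
    def test_canonical_pairs(self, v1, v2, expected):
        assert angular_error(v1, v2) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            angular_error((0, 0, 0), (0, 0, 1))

    @settings(deadline=None, derandomize=True)
    @given(v1=finite3, v2=finite3, scale=st.floats(0.01, 100.0))
    def test_symmetric_scale_invariant_bounded(self, v1, v2, scale):
        a1, a2 = np.array(v1), np.array(v2)
        if np.linalg.norm(a1) < 1e-6 or np.linalg.norm(a2) < 1e-6:
            return
        theta = angular_error(a1, a2)
        assert 0.0 <= theta <= 180.0
        assert angular_error(a2, a1) == pytest.approx(theta, abs=1e-9)
        assert angular_error(scale * a1, a2) == pytest.approx(theta, abs=1e-7)


class TestPinholeCamera:
    cam = CameraModel(fx=500, fy=500, cx=320, cy=288)

    def test_principal_point(self):
        assert np.allclose(backproject(320, 288, 100, self.cam), [0, 0, 100])

    def test_similar_triangles(self):
        cam = CameraModel(fx=500, fy=500, cx=0, cy=0)
        assert np.allclose(backproject(50, 0, 100, cam), [10, 0, 100])

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(InvalidInputError):
            backproject(0, 0, 0.0, self.cam)

    def test_roundtrip_identity(self, rng):
        for _ in range(200):
            p = np.append(rng.uniform(-50, 50, 2), rng.uniform(10, 400))
            u, v, d = project(p, self.cam)
            assert np.allclose(backproject(u, v, d, self.cam), p, atol=1e-9)


def test_vec3_rejects_nonfinite():
    with pytest.raises(InvalidInputError):
        vec3((1.0, np.nan, 0.0))
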