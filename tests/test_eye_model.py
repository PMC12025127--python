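import math

import numpy as np
import pytest

from rgbdgaze.errors import DegenerateGeometryError
from rgbdgaze.eye_model import (
    binocular_gaze,
    chord_midpoint,
    eye_center,
    eye_gaze_ray,
    eye_radius,
    gaze_from_landmarks,
)
from rgbdgaze.geometry import Ray, angular_error, unit

from conftest import random_point, random_rotation


def circumradius(p1, p2, p3) -> float:
    """Independent oracle: circumradius of a triangle from side lengths, R = abc / 4K."""
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    s = (a + b + c) / 2
    area = math.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0))
    return a * b * c / (4 * area)


def arc_configuration(center, radius, half_angle_deg, rotation):
    """Corners at +-alpha on a great circle and the surface point at the arc midpoint."""
    alpha = math.radians(half_angle_deg)
    x, z = rotation.apply([1.0, 0.0, 0.0]), rotation.apply([0.0, 0.0, 1.0])
    c1 = center + radius * (math.sin(alpha) * x + math.cos(alpha) * z)
    c2 = center + radius * (-math.sin(alpha) * x + math.cos(alpha) * z)
    oe_prime = center + radius * z
    return c1, c2, oe_prime


class TestChordMidpoint:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [(((-1, 0, 0)), ((1, 0, 0)), (0, 0, 0)), (((0, 0, 0)), ((0, 2, 0)), (0, 1, 0))],
    )
    def test_examples(self, c1, c2, expected):
        assert np.allclose(chord_midpoint(c1, c2), expected)

    def test_equidistant(self, rng):
        c1, c2 = random_point(rng), random_point(rng)
        mid = chord_midpoint(c1, c2)
        assert abs(np.linalg.norm(mid - c1) - np.linalg.norm(mid - c2)) < 1e-12

    def test_coincident_corners_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            chord_midpoint((1, 2, 3), (1, 2, 3))


class TestEyeRadius:
    def test_diameter_chord(self):
        # corners span a diameter: h = R and c = 2R, so R = h/2 + 4R^2/(8R)
        assert eye_radius((-1.2, 0, 0), (1.2, 0, 0), (0, 0, 1.2)) == pytest.approx(1.2)

    def test_unit_sagitta(self):
        # h = 1, c = 2 -> 0.5 + 4/8 = 1
        assert eye_radius((-1, 0, 0), (1, 0, 0), (0, 0, 1)) == pytest.approx(1.0)

    def test_forty_degree_arc_matches_circumradius_oracle(self):
        r = 1.2
        alpha = math.radians(40)
        c1 = np.array([r * math.sin(alpha), 0, r * math.cos(alpha)])
        c2 = np.array([-r * math.sin(alpha), 0, r * math.cos(alpha)])
        oe_prime = np.array([0.0, 0.0, r])
        assert eye_radius(c1, c2, oe_prime) == pytest.approx(r, abs=1e-9)
        assert eye_radius(c1, c2, oe_prime) == pytest.approx(
            circumradius(c1, c2, oe_prime), abs=1e-9
        )

    def test_rigid_motion_invariance(self, rng):
        for _ in range(50):
            rot = random_rotation(rng)
            t = random_point(rng)
            c1, c2, oe = (random_point(rng, 2) for _ in range(3))
            try:
                r0 = eye_radius(c1, c2, oe)
            except DegenerateGeometryError:
                continue
            r1 = eye_radius(rot.apply(c1) + t, rot.apply(c2) + t, rot.apply(oe) + t)
            assert r1 == pytest.approx(r0, rel=1e-9)

    def test_surface_point_on_chord_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            eye_radius((-1, 0, 0), (1, 0, 0), (0, 0, 1e-9))


class TestEyeCenter:
    def test_diameter_chord_center(self):
        geom = eye_center((-1.2, 0, 0), (1.2, 0, 0), (0, 0, 1.2))
        assert np.allclose(geom.center, [0, 0, 0], atol=1e-12)
        assert geom.radius == pytest.approx(1.2)

    def test_translation_equivariance(self):
        t = np.array([10.0, 20.0, 30.0])
        geom = eye_center(t + (-1.2, 0, 0), t + (1.2, 0, 0), t + (0, 0, 1.2))
        assert np.allclose(geom.center, t, atol=1e-9)

    def test_recovers_generating_sphere_on_200_random_configurations(self, rng):
        """Sphere-fit oracle: center/radius of the generating sphere are recovered
        to < 1e-6 cm whenever the surface point is the circular-arc midpoint."""
        for _ in range(200):
            center = random_point(rng, 50)
            radius = rng.uniform(0.8, 1.6)
            half_angle = rng.uniform(20, 70)
            c1, c2, oe_prime = arc_configuration(center, radius, half_angle, random_rotation(rng))
            geom = eye_center(c1, c2, oe_prime)
            assert np.linalg.norm(geom.center - center) < 1e-6
            assert geom.radius == pytest.approx(radius, abs=1e-6)
            # all defining landmarks lie on the recovered sphere
            for p in (c1, c2, oe_prime):
                assert abs(np.linalg.norm(p - geom.center) - geom.radius) < 1e-6


class TestEyeGazeRay:
    @pytest.mark.parametrize(
        "iris,expected_dir", [((0, 0, -1.2), (0, 0, -1)), ((1.2, 0, 0), (1, 0, 0))]
    )
    def test_axis_through_iris(self, iris, expected_dir):
        geom = eye_center((-1.2, 0, 0), (1.2, 0, 0), (0, 0, 1.2))
        ray = eye_gaze_ray(geom, iris)
        assert np.allclose(ray.origin, geom.center)
        assert np.allclose(ray.direction, expected_dir)

    def test_full_chain_recovers_known_gaze(self, rng):
        for _ in range(50):
            center = random_point(rng, 30)
            radius = rng.uniform(0.9, 1.5)
            rot = random_rotation(rng)
            c1, c2, oe_prime = arc_configuration(center, radius, 40, rot)
            g = unit(rng.standard_normal(3))
            from rgbdgaze.eye_model import EyeLandmarks

            lm = EyeLandmarks(
                corner_1=c1, corner_2=c2, surface_point=oe_prime,
                iris_center=center + radius * g, side="left",
            )
            ray = gaze_from_landmarks(lm)
            assert angular_error(ray.direction, g) < 1e-6

    def test_iris_at_center_rejected(self):
        geom = eye_center((-1.2, 0, 0), (1.2, 0, 0), (0, 0, 1.2))
        with pytest.raises(DegenerateGeometryError):
            eye_gaze_ray(geom, geom.center)


class TestBinocularGaze:
    def test_identical_rays_unchanged(self):
        ray = Ray(origin=(1, 2, 3), direction=(0, 0, -1))
        out = binocular_gaze(ray, ray)
        assert np.allclose(out.origin, ray.origin)
        assert np.allclose(out.direction, ray.direction)

    def test_mirrored_origins(self):
        left = Ray(origin=(-3, 0, 0), direction=(0, 0, -1))
        right = Ray(origin=(3, 0, 0), direction=(0, 0, -1))
        out = binocular_gaze(left, right)
        assert np.allclose(out.origin, [0, 0, 0])
        assert np.allclose(out.direction, [0, 0, -1])

    def test_symmetric_small_convergence_bisects(self):
        eps = 1e-4
        left = Ray(origin=(-3, 0, 0), direction=(math.sin(eps), 0, -math.cos(eps)))
        right = Ray(origin=(3, 0, 0), direction=(-math.sin(eps), 0, -math.cos(eps)))
        out = binocular_gaze(left, right)
        assert np.allclose(out.direction, [0, 0, -1], atol=1e-12)

    def test_antipodal_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            binocular_gaze(
                Ray(origin=(0, 0, 0), direction=(0, 0, 1)),
                Ray(origin=(1, 0, 0), direction=(0, 0, -1)),
            )
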