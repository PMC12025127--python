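"""Geometric primitives for 3D gaze estimation.

All coordinates live in a right-handed camera frame with the camera at the
origin and lengths in centimetres. Points and direction vectors are plain
``numpy`` arrays of shape ``(3,)``; the thin dataclasses below bundle them
into rays, planes, spheres and a pinhole camera model.

A gaze ray is a half-line: intersections are only reported for positive ray
parameter ``t`` (a person cannot gaze backwards through their own head).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InvalidInputError

Vec3 = np.ndarray

_EPS = 1e-12


def vec3(value) -> Vec3:
    """Coerce ``value`` to a finite float64 array of shape (3,)."""
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise InvalidInputError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"non-finite components in {arr!r}")
    return arr


def unit(v) -> Vec3:
    """Normalise ``v`` to unit Euclidean norm; zero vectors are rejected."""
    arr = vec3(v)
    n = float(np.linalg.norm(arr))
    if n < _EPS:
        raise InvalidInputError("cannot normalise a zero vector")
    return arr / n


@dataclass(frozen=True, eq=False)
class Ray:
    """Half-line from ``origin`` along unit ``direction`` (t > 0)."""

    origin: Vec3
    direction: Vec3

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", vec3(self.origin))
        object.__setattr__(self, "direction", unit(self.direction))

    def at(self, t: float) -> Vec3:
        return self.origin + t * self.direction


@dataclass(frozen=True, eq=False)
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: Vec3
    normal: Vec3

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", vec3(self.point))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, p) -> float:
        return float(np.dot(vec3(p) - self.point, self.normal))


@dataclass(frozen=True, eq=False)
class Sphere:
    """Sphere with ``center`` and positive ``radius`` (cm)."""

    center: Vec3
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", vec3(self.center))
        if not (float(self.radius) > 0):
            raise InvalidInputError(f"sphere radius must be > 0, got {self.radius}")
        object.__setattr__(self, "radius", float(self.radius))


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise InvalidInputError("focal lengths must be positive")


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    The normal sign is fixed deterministically: the first of (z, y, x) whose
    magnitude exceeds tolerance is made non-negative, so downstream signed
    quantities do not depend on the order of the defining points.
    """
    p1, p2, p3 = vec3(p1), vec3(p2), vec3(p3)
    n = np.cross(p2 - p1, p3 - p1)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1.0)
    if np.linalg.norm(n) <= 1e-9 * scale * scale:
        raise DegenerateGeometryError("points are collinear or coincident")
    n = n / np.linalg.norm(n)
    for axis in (2, 1, 0):
        if n[axis] > _EPS:
            break
        if n[axis] < -_EPS:
            n = -n
            break
    return Plane(point=p1, normal=n)


def ray_plane_intersection(ray: Ray, plane: Plane) -> Vec3 | None:
    """Intersection of a half-line with a plane, or ``None``.

    ``None`` covers both a ray parallel to the plane and an intersection
    behind the origin (t <= 0); a miss is a normal outcome, not an error.
    """
    denom = float(np.dot(plane.normal, ray.direction))
    if abs(denom) < _EPS:
        return None
    t = float(np.dot(plane.normal, plane.point - ray.origin)) / denom
    if t <= 0.0:
        return None
    return ray.at(t)


def ray_sphere_hit(ray: Ray, sphere: Sphere) -> tuple[bool, Vec3 | None]:
    """Whether the half-line meets the sphere, and the nearest hit point.

    Tangency counts as a hit. Returns ``(False, None)`` on a miss.
    """
    oc = ray.origin - sphere.center
    b = 2.0 * float(np.dot(ray.direction, oc))
    c = float(np.dot(oc, oc)) - sphere.radius**2
    disc = b * b - 4.0 * c
    if disc < 0.0:
        return False, None
    sq = float(np.sqrt(disc))
    t1 = (-b - sq) / 2.0
    t2 = (-b + sq) / 2.0
    t = t1 if t1 > 0.0 else t2
    if t <= 0.0:
        return False, None
    return True, ray.at(t)


def angular_error(v1, v2) -> float:
    """Angle in degrees between two direction vectors, in [0, 180].

    Scale-invariant in both arguments. Computed as atan2(|v1 x v2|, v1 . v2)
    on the normalised vectors, which is exact near 0 deg and 180 deg where the
    arccos form loses precision; the result is identical to
    arccos(clip(v1 . v2 / |v1||v2|, -1, 1)).
    """
    u1, u2 = unit(v1), unit(v2)
    cross = np.linalg.norm(np.cross(u1, u2))
    dot = float(np.dot(u1, u2))
    return float(np.degrees(np.arctan2(cross, dot)))


def project(point, cam: CameraModel) -> tuple[float, float, float]:
    """Forward pinhole projection: 3D point -> (u, v, depth) in px, px, cm."""
    p = vec3(point)
    if p[2] <= 0:
        raise InvalidInputError("point must have positive depth to project")
    u = cam.fx * p[0] / p[2] + cam.cx
    v = cam.fy * p[1] / p[2] + cam.cy
    return float(u), float(v), float(p[2])


def backproject(u: float, v: float, depth: float, cam: CameraModel) -> Vec3:
    """Pinhole back-projection of a pixel with known depth into the camera frame."""
    if not depth > 0:
        raise InvalidInputError(f"depth must be > 0, got {depth}")
    x = (u - cam.cx) * depth / cam.fx
    y = (v - cam.cy) * depth / cam.fy
    return np.array([x, y, depth], dtype=float)
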