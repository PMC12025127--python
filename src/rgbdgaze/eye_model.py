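"""Eyeball-center gaze estimation from eye-surface landmarks.

The eyeball is modelled as a sphere. From two eye-corner landmarks C1, C2
and a frontal eye-surface point Oe' the sphere radius follows the classic
sagitta-chord relation

    R = h/2 + c^2 / (8 h),    h = |Oe' - C|,  c = |C1 - C2|,

where C is the chord midpoint. The construction is exact when Oe' is the
arc midpoint over the chord (Oe'C perpendicular to C1C2); with noisy
landmarks the midpoint approximation is used as-is and the error surfaces
in the noise-sensitivity tests rather than being hidden.

The eye center Oe lies on the line Oe'C at distance R behind the surface
point, and the gaze ray is the anatomical axis through the iris center:
origin Oe, direction Oe -> Oi. No kappa-angle (optical vs visual axis)
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .geometry import Ray, Vec3, unit, vec3

#: Default adult eyeball radius in cm, used by the synthetic generator.
DEFAULT_EYEBALL_RADIUS_CM = 1.2

_H_MIN_CM = 1e-6


@dataclass(frozen=True, eq=False)
class EyeLandmarks:
    """One eye's landmark set: two corners, a frontal surface point, the iris center."""

    corner_1: Vec3
    corner_2: Vec3
    surface_point: Vec3
    iris_center: Vec3
    side: str  # "left" | "right"

    def __post_init__(self) -> None:
        for name in ("corner_1", "corner_2", "surface_point", "iris_center"):
            object.__setattr__(self, name, vec3(getattr(self, name)))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass(frozen=True, eq=False)
class EyeGeometry:
    """Recovered eyeball sphere: center, radius (cm) and the chord midpoint used."""

    center: Vec3
    radius: float
    chord_midpoint: Vec3


def chord_midpoint(c1, c2) -> Vec3:
    """Midpoint of the eye-corner chord C1C2."""
    c1, c2 = vec3(c1), vec3(c2)
    if np.linalg.norm(c1 - c2) < _H_MIN_CM:
        raise DegenerateGeometryError("eye corners coincide")
    return (c1 + c2) / 2.0


def eye_radius(c1, c2, oe_prime) -> float:
    """Eyeball radius from the sagitta-chord relation R = h/2 + c^2/(8h)."""
    c1, c2 = vec3(c1), vec3(c2)
    mid = chord_midpoint(c1, c2)
    h = float(np.linalg.norm(vec3(oe_prime) - mid))
    if h < _H_MIN_CM:
        raise DegenerateGeometryError("surface point collapsed onto the chord midpoint")
    c = float(np.linalg.norm(c1 - c2))
    return h / 2.0 + c * c / (8.0 * h)


def eye_center(c1, c2, oe_prime) -> EyeGeometry:
    """Eyeball center: R along the surface-to-chord-midpoint direction from Oe'."""
    oe_prime = vec3(oe_prime)
    mid = chord_midpoint(c1, c2)
    radius = eye_radius(c1, c2, oe_prime)
    center = oe_prime + radius * unit(mid - oe_prime)
    return EyeGeometry(center=center, radius=radius, chord_midpoint=mid)


def eye_gaze_ray(geom: EyeGeometry, iris_center) -> Ray:
    """Anatomical-axis gaze ray: from the eye center through the iris center."""
    iris = vec3(iris_center)
    if np.linalg.norm(iris - geom.center) < _H_MIN_CM:
        raise DegenerateGeometryError("iris center coincides with the eye center")
    return Ray(origin=geom.center, direction=iris - geom.center)


def binocular_gaze(left: Ray, right: Ray) -> Ray:
    """Combine two monocular rays: midpoint origin, normalised mean direction."""
    s = left.direction + right.direction
    if np.linalg.norm(s) < 1e-9:
        raise DegenerateGeometryError("monocular gaze directions are antipodal")
    return Ray(origin=(left.origin + right.origin) / 2.0, direction=s)


def gaze_from_landmarks(lm: EyeLandmarks) -> Ray:
    """Full monocular chain: landmarks -> eye sphere -> anatomical-axis ray."""
    geom = eye_center(lm.corner_1, lm.corner_2, lm.surface_point)
    return eye_gaze_ray(geom, lm.iris_center)
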