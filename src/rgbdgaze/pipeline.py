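"""Per-frame gaze estimation with distance-gated method switching.

Close to the camera (head depth <= 70 cm by default) eye landmarks are
detailed enough for the eyeball-center method; farther away the skeletal
head-orientation method is more reliable. The gate compares the camera-frame
depth (|Z| of the face center MN) against the threshold — the configured
"positions" of the measurement protocol (55–340 cm) are depths, not
Euclidean ranges.

For every frame the selected gaze ray is intersected with the target plane
and with the configured head spheres; failures never abort a stream, they
are encoded in the emitted estimate (``valid=False`` frames are kept so
interaction-period denominators stay correct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import eye_model, head_pose
from .errors import (
    DegenerateGeometryError,
    InputOrderError,
    InvalidFrameError,
    InvalidInputError,
    RecoveryFailedError,
)
from .eye_model import EyeLandmarks
from .geometry import (
    Plane,
    Ray,
    Sphere,
    Vec3,
    plane_from_points,
    ray_plane_intersection,
    ray_sphere_hit,
    vec3,
)
from .head_pose import HeadFrameTemplate, HeadJoints

#: Target-board landmark coordinates (cm, camera frame): seven targets on a
#: board parallel to the camera X-Y plane at Z = -398.3 cm.
TARGET_BOARD_CM: dict[str, tuple[float, float, float]] = {
    "target_1": (603.5, 427.3, -398.3),
    "target_2": (603.5, 0.0, -398.3),
    "target_3": (603.5, -432.7, -398.3),
    "target_4": (0.0, -432.7, -398.3),
    "target_5": (-576.5, -432.7, -398.3),
    "target_6": (-576.5, 0.0, -398.3),
    "target_7": (-576.5, 432.7, -398.3),
}

#: Subject positions of the target-board protocol (cm): five depths 55-340.
PARTICIPANT_POSITIONS_CM: dict[int, tuple[float, float, float]] = {
    1: (0.0, 143.0, 55.0),
    2: (0.0, 143.0, 120.0),
    3: (76.0, 143.0, 194.0),
    4: (-75.0, 143.0, 284.0),
    5: (0.0, 143.0, 340.0),
}

DEFAULT_GATE_CM = 70.0
DEFAULT_HEAD_SPHERE_RADIUS_CM = 12.0


@dataclass(frozen=True, eq=False)
class Frame:
    """One timestamped observation of one person."""

    timestamp: float
    person_id: str
    head: HeadJoints
    eyes: dict[str, EyeLandmarks] | None = None  # keys "left"/"right"

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise InvalidInputError(f"timestamp must be >= 0, got {self.timestamp}")


@dataclass(frozen=True)
class HeadSphereSpec:
    """A gaze target sphere: either anchored to a person's MN or at a fixed center."""

    radius: float = DEFAULT_HEAD_SPHERE_RADIUS_CM
    person: str | None = None
    center: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if (self.person is None) == (self.center is None):
            raise InvalidInputError("sphere spec needs exactly one of person / center")
        if not self.radius > 0:
            raise InvalidInputError("sphere radius must be > 0")


@dataclass(eq=False)
class SceneConfig:
    """Scene geometry and gating for a session."""

    plane_points: tuple | None = None  # three Point3 defining the target plane
    targets: dict[str, Vec3] = field(default_factory=dict)
    spheres: dict[str, HeadSphereSpec] = field(default_factory=dict)
    gate_cm: float = DEFAULT_GATE_CM

    def __post_init__(self) -> None:
        if not self.gate_cm > 0:
            raise InvalidInputError("gate_cm must be > 0")
        if self.plane_points is not None:
            self.plane_points = tuple(vec3(p) for p in self.plane_points)
            if len(self.plane_points) != 3:
                raise InvalidInputError("plane_points needs exactly three points")
        self.targets = {k: vec3(v) for k, v in self.targets.items()}

    @property
    def plane(self) -> Plane | None:
        if self.plane_points is None:
            return None
        return plane_from_points(*self.plane_points)

    @classmethod
    def target_board_default(cls) -> "SceneConfig":
        """The seven-target board scene used by the measurement protocol."""
        targets = {k: np.array(v) for k, v in TARGET_BOARD_CM.items()}
        return cls(
            plane_points=(
                targets["target_1"],
                targets["target_4"],
                targets["target_7"],
            ),
            targets=targets,
        )


@dataclass(frozen=True, eq=False)
class GazeEstimate:
    """Per-frame result: the chosen method, the ray, and target intersections."""

    timestamp: float
    person_id: str
    method: str  # "eye" | "head" | "none"
    valid: bool
    ray: Ray | None = None
    plane_hit: Vec3 | None = None
    sphere_hits: dict[str, bool] = field(default_factory=dict)
    gating_distance: float | None = None
    fallback: bool = False  # eye method was gated on but unavailable


def _resolve_head(frame: Frame, template: HeadFrameTemplate | None) -> HeadJoints | None:
    joints = frame.head
    if all(head_pose.joint_valid(j) for j in joints.joints()):
        return joints
    if template is None:
        return None
    try:
        return head_pose.rigid_recover(template, joints)
    except RecoveryFailedError:
        return None


def gating_distance(frame: Frame, template: HeadFrameTemplate | None = None) -> float:
    """Camera-frame depth of the face center MN, as a nonnegative magnitude (cm)."""
    joints = _resolve_head(frame, template)
    if joints is None:
        raise InvalidFrameError("no usable head estimate for gating")
    _, mn = head_pose.head_centers(joints)
    return abs(float(mn[2]))


def _eye_ray(frame: Frame) -> Ray | None:
    """Binocular gaze ray, degrading to monocular when one eye fails."""
    if not frame.eyes:
        return None
    rays = []
    for side in ("left", "right"):
        lm = frame.eyes.get(side)
        if lm is None:
            continue
        try:
            rays.append(eye_model.gaze_from_landmarks(lm))
        except DegenerateGeometryError:
            continue
    if not rays:
        return None
    if len(rays) == 1:
        return rays[0]
    try:
        return eye_model.binocular_gaze(rays[0], rays[1])
    except DegenerateGeometryError:
        return None


def estimate_frame(
    frame: Frame,
    scene: SceneConfig,
    template: HeadFrameTemplate | None = None,
    sphere_centers: dict[str, Vec3] | None = None,
    force_method: str | None = None,
) -> GazeEstimate:
    """Estimate one frame's gaze and its target intersections.

    ``sphere_centers`` supplies the current MN of each person for
    person-anchored spheres; spheres anchored to the gazer themself or to an
    unseen person score ``False``. ``force_method`` ("eye" | "head") disables
    the distance gate, as used for method comparisons.
    """
    if force_method not in (None, "eye", "head"):
        raise InvalidInputError(f"force_method must be 'eye' or 'head', got {force_method!r}")
    joints = _resolve_head(frame, template)
    distance: float | None = None
    head_ray: Ray | None = None
    if joints is not None:
        try:
            head_ray = head_pose.head_gaze_ray(joints)
            _, mn = head_pose.head_centers(joints)
            distance = abs(float(mn[2]))
        except (DegenerateGeometryError, InvalidFrameError):
            head_ray = None

    eye_wanted = (
        force_method == "eye"
        if force_method
        else (distance is None or distance <= scene.gate_cm)
    )
    ray: Ray | None = None
    method = "none"
    fallback = False
    if eye_wanted:
        ray = _eye_ray(frame)
        if ray is not None:
            method = "eye"
        elif force_method != "eye" and head_ray is not None:
            ray, method, fallback = head_ray, "head", True
    elif force_method != "eye" and head_ray is not None:
        ray, method = head_ray, "head"

    if ray is None:
        return GazeEstimate(
            timestamp=frame.timestamp,
            person_id=frame.person_id,
            method="none",
            valid=False,
            gating_distance=distance,
            fallback=fallback,
        )

    plane = scene.plane
    plane_hit = ray_plane_intersection(ray, plane) if plane is not None else None
    sphere_hits: dict[str, bool] = {}
    for name, spec in scene.spheres.items():
        if spec.center is not None:
            center = vec3(spec.center)
        else:
            if spec.person == frame.person_id:
                continue  # a person cannot gaze at their own head sphere
            center = (sphere_centers or {}).get(spec.person)
        if center is None:
            sphere_hits[name] = False
            continue
        hit, _ = ray_sphere_hit(ray, Sphere(center=center, radius=spec.radius))
        sphere_hits[name] = hit

    return GazeEstimate(
        timestamp=frame.timestamp,
        person_id=frame.person_id,
        method=method,
        valid=True,
        ray=ray,
        plane_hit=plane_hit,
        sphere_hits=sphere_hits,
        gating_distance=distance,
        fallback=fallback,
    )


def run_stream(
    frames,
    scene: SceneConfig,
    force_method: str | None = None,
) -> list[GazeEstimate]:
    """Estimate a whole stream, maintaining per-person head templates.

    The template for a person is refreshed whenever all five joints score
    >= 2 and is never updated from recovered frames. Person-anchored spheres
    use each person's most recently resolved MN. Frames must be sorted by
    timestamp within each person.
    """
    templates: dict[str, HeadFrameTemplate] = {}
    last_mn: dict[str, Vec3] = {}
    last_t: dict[str, float] = {}
    out: list[GazeEstimate] = []
    for frame in frames:
        prev = last_t.get(frame.person_id)
        if prev is not None and frame.timestamp < prev:
            raise InputOrderError(
                f"timestamps for {frame.person_id!r} decrease at t={frame.timestamp}"
            )
        last_t[frame.person_id] = frame.timestamp
        template = templates.get(frame.person_id)
        est = estimate_frame(
            frame, scene, template=template, sphere_centers=last_mn, force_method=force_method
        )
        out.append(est)
        joints = _resolve_head(frame, template)
        if joints is not None:
            _, mn = head_pose.head_centers(joints)
            last_mn[frame.person_id] = mn
        fresh = head_pose.template_from(frame.head)
        if fresh is not None:
            templates[frame.person_id] = fresh
    return out
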