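"""Synthetic Azure-Kinect-style landmark streams with known ground truth.

Two scene families are generated, both at 30 FPS by default:

* **target-board sessions** — a single subject at one of the five protocol
  depths (55-340 cm) fixates one of the seven board targets; head joints
  are a rigid template rotated so the ME->MN axis points exactly at the
  target, and eye landmarks sit on eyeball spheres with the iris displaced
  along the true gaze, so at zero noise both estimators recover the gaze
  exactly;
* **two-person interaction sessions** — a child and a clinician face each
  other; during scheduled intervals the gazer's head is oriented at the
  other person's face center MN, otherwise at a fixed away-point, so the
  scripted schedule is the exact ground truth for period extraction.

Corruption models: isotropic Gaussian noise (sigma, cm) added per landmark
coordinate, and independent demotion of each head joint to confidence 1
(the occlusion-predicted score) with a configurable probability. The same
standard-normal draws are scaled by sigma, so one seed yields a noise field
that grows continuously with sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InvalidInputError
from .eye_model import DEFAULT_EYEBALL_RADIUS_CM, EyeLandmarks
from .geometry import Vec3, unit, vec3
from .head_pose import JOINT_NAMES, HeadJoints, JointObservation
from .interaction import TimeInterval
from .pipeline import PARTICIPANT_POSITIONS_CM, TARGET_BOARD_CM, Frame

#: Rest-pose joint offsets (cm) relative to the head center; anatomically
#: plausible proportions, forward = -z in the rest frame.
DEFAULT_HEAD_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "eye_right": (3.0, 0.0, -8.0),
    "eye_left": (-3.0, 0.0, -8.0),
    "nose": (0.0, -4.0, -10.0),
    "ear_right": (7.0, 1.0, 0.0),
    "ear_left": (-7.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the measurement protocol."""

    fps: float = 30.0
    duration_s: float = 10.0
    subject_position: tuple[float, float, float] = PARTICIPANT_POSITIONS_CM[1]
    eyeball_radius_cm: float = DEFAULT_EYEBALL_RADIUS_CM
    corner_half_angle_deg: float = 40.0
    head_template: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HEAD_TEMPLATE)
    )
    noise_sigma_cm: float = 0.0
    dropout_prob: float = 0.0
    include_eyes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise InvalidInputError("fps must be > 0")
        if self.noise_sigma_cm < 0:
            raise InvalidInputError("noise sigma must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise InvalidInputError("dropout probability must be in [0, 1]")
        if set(self.head_template) != set(JOINT_NAMES):
            raise InvalidInputError(f"head template must define exactly {JOINT_NAMES}")


@dataclass(frozen=True)
class FrameTruth:
    """Noise-free ground truth for one generated frame."""

    timestamp: float
    person_id: str
    gaze_direction: Vec3  # true direction of the method the gate selects
    head_direction: Vec3  # true ME->MN direction
    target_point: Vec3
    target_id: str | None = None


@dataclass(frozen=True)
class GroundTruth:
    """Ground truth for a generated stream."""

    frames: tuple[FrameTruth, ...]
    schedules: dict[str, tuple[TimeInterval, ...]] = field(default_factory=dict)


def _template_arrays(template: dict) -> tuple[np.ndarray, Vec3, Vec3]:
    """(5,3) offsets in JOINT_NAMES order plus rest-pose ME and MN."""
    offsets = np.array([template[name] for name in JOINT_NAMES], dtype=float)
    me = (offsets[JOINT_NAMES.index("ear_right")] + offsets[JOINT_NAMES.index("ear_left")]) / 2
    mn = (
        offsets[JOINT_NAMES.index("eye_right")]
        + offsets[JOINT_NAMES.index("eye_left")]
        + offsets[JOINT_NAMES.index("nose")]
    ) / 3
    return offsets, me, mn


def _minimal_rotation(a: Vec3, b: Vec3) -> Rotation:
    """Smallest rotation taking unit vector ``a`` onto unit vector ``b``."""
    v = np.cross(a, b)
    s = float(np.linalg.norm(v))
    c = float(np.dot(a, b))
    if s < 1e-15:
        if c > 0:
            return Rotation.identity()
        # antipodal: rotate 180 deg about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(math.pi * unit(axis))
    return Rotation.from_rotvec(math.atan2(s, c) * (v / s))


def _aim_head(
    head_center: Vec3, target: Vec3, template: dict, tol: float = 1e-13, max_iter: int = 100
) -> Rotation:
    """Rotation placing the template so its ME->MN axis points at ``target``.

    The ray origin MN itself moves with the rotation, so the aim is solved
    by fixed-point iteration; it converges to machine precision in a few
    steps for targets outside the head.
    """
    _, me_t, mn_t = _template_arrays(template)
    forward = unit(mn_t - me_t)
    if np.linalg.norm(target - head_center) < 30.0:
        raise DegenerateGeometryError("gaze target inside or too close to the head")
    rot = Rotation.identity()
    for _ in range(max_iter):
        mn_world = head_center + rot.apply(mn_t)
        desired = unit(target - mn_world)
        current = rot.apply(forward)
        step = _minimal_rotation(current, desired)
        rot = step * rot
        if np.linalg.norm(np.cross(rot.apply(forward), unit(target - (head_center + rot.apply(mn_t))))) < tol:
            break
    return rot


def _noise(rng: np.random.Generator, sigma: float) -> Vec3:
    # draw unconditionally so one seed gives sigma-scaled realisations
    return sigma * rng.standard_normal(3)


def _make_person_frame(
    cfg: SyntheticConfig,
    person_id: str,
    head_center: Vec3,
    target: Vec3,
    timestamp: float,
    rng: np.random.Generator,
    include_eyes: bool,
    target_id: str | None = None,
    rot: Rotation | None = None,
) -> tuple[Frame, FrameTruth]:
    if rot is None:
        rot = _aim_head(head_center, target, cfg.head_template)
    offsets, _, mn_t = _template_arrays(cfg.head_template)
    world = head_center + rot.apply(offsets)
    mn_world = head_center + rot.apply(mn_t)
    head_direction = unit(target - mn_world)

    joints = {}
    for i, name in enumerate(JOINT_NAMES):
        conf = 1 if rng.random() < cfg.dropout_prob else 3
        joints[name] = JointObservation(
            position=world[i] + _noise(rng, cfg.noise_sigma_cm), confidence=conf
        )
    head = HeadJoints(**joints)

    eyes = None
    gaze_direction = head_direction
    if include_eyes:
        eyes = {}
        r = cfg.eyeball_radius_cm
        alpha = math.radians(cfg.corner_half_angle_deg)
        x_head = rot.apply([1.0, 0.0, 0.0])
        f_head = rot.apply([0.0, 0.0, -1.0])  # rest-pose forward axis of the head
        true_dirs = []
        for side, name in (("right", "eye_right"), ("left", "eye_left")):
            center = head_center + rot.apply(np.asarray(cfg.head_template[name], dtype=float))
            g = unit(target - center)
            true_dirs.append(g)
            corner_1 = center + r * (math.sin(alpha) * x_head + math.cos(alpha) * f_head)
            corner_2 = center + r * (-math.sin(alpha) * x_head + math.cos(alpha) * f_head)
            surface = center + r * f_head  # Oe' on the head-forward axis
            iris = center + r * g
            eyes[side] = EyeLandmarks(
                corner_1=corner_1 + _noise(rng, cfg.noise_sigma_cm),
                corner_2=corner_2 + _noise(rng, cfg.noise_sigma_cm),
                surface_point=surface + _noise(rng, cfg.noise_sigma_cm),
                iris_center=iris + _noise(rng, cfg.noise_sigma_cm),
                side=side,
            )
        # true binocular direction under the midpoint/mean-direction convention
        gaze_direction = unit(true_dirs[0] + true_dirs[1])

    frame = Frame(timestamp=timestamp, person_id=person_id, head=head, eyes=eyes)
    truth = FrameTruth(
        timestamp=timestamp,
        person_id=person_id,
        gaze_direction=gaze_direction if include_eyes else head_direction,
        head_direction=head_direction,
        target_point=vec3(target),
        target_id=target_id,
    )
    return frame, truth


def make_subject_frame(
    cfg: SyntheticConfig,
    gaze_target,
    rng: np.random.Generator,
    timestamp: float = 0.0,
    person_id: str = "subject",
    target_id: str | None = None,
) -> tuple[Frame, FrameTruth]:
    """One frame of a single subject fixating ``gaze_target``."""
    return _make_person_frame(
        cfg,
        person_id,
        vec3(cfg.subject_position),
        vec3(gaze_target),
        timestamp,
        rng,
        include_eyes=cfg.include_eyes,
        target_id=target_id,
    )


def make_subject_session(
    cfg: SyntheticConfig, target_id: str = "target_4", n_frames: int | None = None
) -> tuple[list[Frame], GroundTruth]:
    """A fixation session on one named board target (seeded from the config)."""
    if target_id not in TARGET_BOARD_CM:
        raise InvalidInputError(f"unknown target {target_id!r}")
    target = vec3(TARGET_BOARD_CM[target_id])
    rng = np.random.default_rng(cfg.seed)
    if n_frames is None:
        n_frames = int(round(cfg.duration_s * cfg.fps))
    frames, truths = [], []
    for k in range(n_frames):
        frame, truth = make_subject_frame(
            cfg, target, rng, timestamp=k / cfg.fps, target_id=target_id
        )
        frames.append(frame)
        truths.append(truth)
    return frames, GroundTruth(frames=tuple(truths))


@dataclass(frozen=True)
class InteractionConfig:
    """Two-person scene layout for scripted gaze sessions."""

    person_a: str = "child"
    person_b: str = "clinician"
    position_a: tuple[float, float, float] = (-50.0, 0.0, 150.0)
    position_b: tuple[float, float, float] = (50.0, 0.0, 150.0)
    away_point: tuple[float, float, float] = (0.0, 200.0, -300.0)


def _active(schedule: tuple[TimeInterval, ...], second: int) -> bool:
    return any(p.start <= second <= p.end for p in schedule)


def _validate_schedule(schedule, duration_s: float, label: str) -> tuple[TimeInterval, ...]:
    periods = tuple(sorted(schedule))
    for a, b in zip(periods, periods[1:]):
        if b.start <= a.end:
            raise InvalidInputError(f"{label} schedule periods overlap")
    for p in periods:
        if p.end >= duration_s:
            raise InvalidInputError(f"{label} schedule exceeds session duration")
    return periods


def make_interaction_session(
    schedule_a_to_b,
    schedule_b_to_a,
    cfg: SyntheticConfig,
    layout: InteractionConfig = InteractionConfig(),
    active_seconds=None,
) -> tuple[list[Frame], GroundTruth]:
    """Two-person session with scripted mutual-gaze schedules.

    Schedules are closed whole-second intervals: the gazer is oriented at
    the other person's MN for every frame whose second falls inside a
    scheduled period, and at the away-point otherwise. ``active_seconds``
    optionally restricts generation to a set of seconds (long, mostly empty
    timelines are then sparse; absent seconds simply binarise to non-hits).
    """
    sched_ab = _validate_schedule(schedule_a_to_b, cfg.duration_s, "a_to_b")
    sched_ba = _validate_schedule(schedule_b_to_a, cfg.duration_s, "b_to_a")
    rng = np.random.default_rng(cfg.seed)
    pa, pb = vec3(layout.position_a), vec3(layout.position_b)
    away = vec3(layout.away_point)
    _, _, mn_t = _template_arrays(cfg.head_template)

    n_frames = int(round(cfg.duration_s * cfg.fps))
    frames: list[Frame] = []
    truths: list[FrameTruth] = []
    interaction_cfg = replace(cfg, include_eyes=False)

    # Both heads are static apart from rotation, so only four gaze
    # configurations exist; solve each joint aim fixed-point once.
    pose_cache: dict[tuple[bool, bool], tuple] = {}

    def _poses(a_gazes: bool, b_gazes: bool):
        key = (a_gazes, b_gazes)
        if key not in pose_cache:
            # Joint fixed-point for the two aims: each person's target is
            # the other's actual MN, which moves as they rotate to aim.
            mn_a, mn_b = pa + mn_t, pb + mn_t
            for _ in range(8):
                rot_a = _aim_head(pa, mn_b if a_gazes else away, cfg.head_template)
                rot_b = _aim_head(pb, mn_a if b_gazes else away, cfg.head_template)
                mn_a = pa + rot_a.apply(mn_t)
                mn_b = pb + rot_b.apply(mn_t)
            pose_cache[key] = (rot_a, rot_b, mn_a, mn_b)
        return pose_cache[key]

    for k in range(n_frames):
        t = k / cfg.fps
        second = int(math.floor(t))
        if active_seconds is not None and second not in active_seconds:
            continue
        a_gazes = _active(sched_ab, second)
        b_gazes = _active(sched_ba, second)
        rot_a, rot_b, mn_a, mn_b = _poses(a_gazes, b_gazes)
        # clinician first so the child's frame sees the same-timestamp MN
        for person, center, target, tid, rot in (
            (layout.person_b, pb, mn_a if b_gazes else away, layout.person_a if b_gazes else None, rot_b),
            (layout.person_a, pa, mn_b if a_gazes else away, layout.person_b if a_gazes else None, rot_a),
        ):
            frame, truth = _make_person_frame(
                interaction_cfg,
                person,
                center,
                target,
                t,
                rng,
                include_eyes=False,
                target_id=tid,
                rot=rot,
            )
            frames.append(frame)
            truths.append(truth)
    return frames, GroundTruth(
        frames=tuple(truths),
        schedules={
            f"{layout.person_a}->{layout.person_b}": sched_ab,
            f"{layout.person_b}->{layout.person_a}": sched_ba,
        },
    )
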