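"""Head-orientation gaze from five skeletal face joints.

The five joints are the left/right eyes, left/right ears and the nose, each
carrying an Azure-Kinect-style confidence score in {0, 1, 2, 3} (0 out of
range, 1 occlusion-predicted, 2 moderate, 3 high). A joint is trusted only
when its score is >= 2.

Because the five points are rigid on the skull, a joint lost to occlusion
can be recovered from the most recent fully observed frame: a least-squares
rigid transform (Kabsch, rotation + translation, no scaling, reflection
guarded) is fitted on the >= 3 trusted correspondences and applied to the
template position of each missing joint.

The gaze axis runs from ME (midpoint of the ears) through MN (centroid of
the two eyes and the nose); using MN rather than the eyes alone compensates
for the upward tilt caused by the eye-ear height difference and provides a
natural face-center origin for the ray.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidFrameError, RecoveryFailedError
from .geometry import Ray, Vec3, vec3

JOINT_NAMES = ("eye_right", "eye_left", "nose", "ear_right", "ear_left")

CONFIDENCE_VALID = 2


@dataclass(frozen=True, eq=False)
class JointObservation:
    """A 3D joint with its detection confidence; ``recovered`` marks filled-in joints."""

    position: Vec3
    confidence: int
    recovered: bool = False

    def __post_init__(self) -> None:
        if self.confidence not in (0, 1, 2, 3):
            raise ValueError(f"confidence must be in 0..3, got {self.confidence}")
        if self.confidence >= 1:
            object.__setattr__(self, "position", vec3(self.position))


@dataclass(frozen=True, eq=False)
class HeadJoints:
    """The five face joints: eyes (N1, N2), nose (N3), ears (E1, E2)."""

    eye_right: JointObservation
    eye_left: JointObservation
    nose: JointObservation
    ear_right: JointObservation
    ear_left: JointObservation

    def joints(self) -> tuple[JointObservation, ...]:
        return tuple(getattr(self, name) for name in JOINT_NAMES)

    def positions(self) -> np.ndarray:
        """(5, 3) array of joint positions in JOINT_NAMES order."""
        return np.array([j.position for j in self.joints()], dtype=float)

    def all_usable(self) -> bool:
        return all(joint_valid(j) or j.recovered for j in self.joints())


@dataclass(frozen=True, eq=False)
class HeadFrameTemplate:
    """Joint positions from the last frame where all five scored >= 2."""

    positions: np.ndarray  # (5, 3), JOINT_NAMES order

    def __post_init__(self) -> None:
        arr = np.asarray(self.positions, dtype=float)
        if arr.shape != (5, 3) or not np.all(np.isfinite(arr)):
            raise ValueError("template needs five finite 3D joint positions")
        object.__setattr__(self, "positions", arr)


def joint_valid(j: JointObservation) -> bool:
    """A joint is well detected iff its confidence score is >= 2."""
    return j.confidence >= CONFIDENCE_VALID


def template_from(joints: HeadJoints) -> HeadFrameTemplate | None:
    """A fresh template if every joint is trusted (never built from recovered joints)."""
    if all(joint_valid(j) and not j.recovered for j in joints.joints()):
        return HeadFrameTemplate(positions=joints.positions())
    return None


def rigid_fit(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping source points onto target.

    Kabsch via SVD of the cross-covariance; the rotation determinant is
    forced to +1 so a reflection can never be returned.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    h = (src - sc).T @ (tgt - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tc - rot @ sc
    return rot, t


def rigid_recover(template: HeadFrameTemplate, current: HeadJoints) -> HeadJoints:
    """Fill occlusion-predicted joints by rigidly moving the template.

    Requires at least three trusted, non-collinear joints in the current
    frame; trusted joints pass through unchanged, the rest are replaced by
    the transformed template positions and flagged ``recovered``.
    """
    valid_idx = [i for i, j in enumerate(current.joints()) if joint_valid(j)]
    if len(valid_idx) == 5:
        return current
    if len(valid_idx) < 3:
        raise RecoveryFailedError(
            f"only {len(valid_idx)} trusted joints; rigid recovery needs >= 3"
        )
    src = template.positions[valid_idx]
    tgt = np.array([current.joints()[i].position for i in valid_idx])
    centered = src - src.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        raise RecoveryFailedError("trusted joints are collinear; rotation underdetermined")
    rot, t = rigid_fit(src, tgt)
    fields = {}
    for i, name in enumerate(JOINT_NAMES):
        j = getattr(current, name)
        if joint_valid(j):
            fields[name] = j
        else:
            fields[name] = JointObservation(
                position=rot @ template.positions[i] + t,
                confidence=j.confidence,
                recovered=True,
            )
    return HeadJoints(**fields)


def head_centers(joints: HeadJoints) -> tuple[Vec3, Vec3]:
    """(ME, MN): ear midpoint and eyes+nose centroid."""
    if not joints.all_usable():
        raise InvalidFrameError("head joints contain unrecovered invalid joints")
    me = (joints.ear_right.position + joints.ear_left.position) / 2.0
    mn = (
        joints.eye_right.position + joints.eye_left.position + joints.nose.position
    ) / 3.0
    return me, mn


def head_gaze_ray(joints: HeadJoints) -> Ray:
    """Head-orientation gaze ray: origin MN, direction ME -> MN."""
    me, mn = head_centers(joints)
    return Ray(origin=mn, direction=mn - me)


def demote(joints: HeadJoints, names: tuple[str, ...], confidence: int = 1) -> HeadJoints:
    """Copy of ``joints`` with the named joints demoted to the given confidence."""
    return replace(
        joints,
        **{n: replace(getattr(joints, n), confidence=confidence) for n in names},
    )
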