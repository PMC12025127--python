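"""File formats: frame JSONL, gaze-estimate JSONL, periods CSV, scene YAML.

Frame streams use JSON lines (one frame object per line) so that hour-long
sessions can be streamed and appended. Period lists are CSV with times in
either ``MM:SS`` or ``MM min SS s`` dialects. Scene and run configuration
is YAML. Schema violations raise :class:`~rgbdgaze.errors.DataFormatError`
with the offending line number.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataFormatError, InvalidInputError
from .eye_model import EyeLandmarks
from .head_pose import JOINT_NAMES, HeadJoints, JointObservation
from .interaction import TimeInterval
from .pipeline import Frame, GazeEstimate, HeadSphereSpec, SceneConfig

_MMSS_COLON = re.compile(r"^\s*(\d+):(\d{1,2})\s*$")
_MMSS_WORDS = re.compile(r"^\s*(\d+)\s*min\s*(\d+)\s*s\s*$")
_SECONDS = re.compile(r"^\s*(\d+)\s*$")


def parse_mmss(text) -> int:
    """Parse ``MM:SS``, ``MM min SS s`` or plain seconds into integer seconds."""
    s = str(text)
    for pattern in (_MMSS_COLON, _MMSS_WORDS):
        m = pattern.match(s)
        if m:
            mins, secs = int(m.group(1)), int(m.group(2))
            if secs >= 60:
                raise InvalidInputError(f"seconds field out of range in {text!r}")
            return mins * 60 + secs
    m = _SECONDS.match(s)
    if m:
        return int(m.group(1))
    raise InvalidInputError(f"cannot parse time {text!r}")


def format_mmss(seconds: float) -> str:
    total = int(round(seconds))
    return f"{total // 60}:{total % 60:02d}"


# ---------------------------------------------------------------------------
# Frame JSONL

_FRAME_KEYS = {"t", "person", "joints", "eyes"}
_JOINT_KEYS = {"name", "x", "y", "z", "conf"}
_EYE_KEYS = {"side", "c1", "c2", "surface", "iris"}


def _xyz(obj, what: str) -> list[float]:
    if not (isinstance(obj, (list, tuple)) and len(obj) == 3):
        raise ValueError(f"{what} must be an [x, y, z] triple")
    return [float(v) for v in obj]


def frame_to_record(frame: Frame) -> dict:
    joints = []
    for name in JOINT_NAMES:
        j = getattr(frame.head, name)
        x, y, z = (float(v) for v in j.position)
        joints.append({"name": name, "x": x, "y": y, "z": z, "conf": j.confidence})
    rec: dict = {"t": frame.timestamp, "person": frame.person_id, "joints": joints}
    if frame.eyes:
        rec["eyes"] = [
            {
                "side": lm.side,
                "c1": [float(v) for v in lm.corner_1],
                "c2": [float(v) for v in lm.corner_2],
                "surface": [float(v) for v in lm.surface_point],
                "iris": [float(v) for v in lm.iris_center],
            }
            for lm in (frame.eyes.get("left"), frame.eyes.get("right"))
            if lm is not None
        ]
    return rec


def frame_from_record(rec: dict) -> Frame:
    unknown = set(rec) - _FRAME_KEYS
    if unknown:
        raise ValueError(f"unknown frame fields {sorted(unknown)}")
    joints: dict[str, JointObservation] = {}
    for j in rec["joints"]:
        unknown = set(j) - _JOINT_KEYS
        if unknown:
            raise ValueError(f"unknown joint fields {sorted(unknown)}")
        if j["name"] not in JOINT_NAMES:
            raise ValueError(f"unknown joint name {j['name']!r}")
        joints[j["name"]] = JointObservation(
            position=[j["x"], j["y"], j["z"]], confidence=int(j["conf"])
        )
    missing = set(JOINT_NAMES) - set(joints)
    if missing:
        raise ValueError(f"missing joints {sorted(missing)}")
    eyes = None
    if rec.get("eyes"):
        eyes = {}
        for e in rec["eyes"]:
            unknown = set(e) - _EYE_KEYS
            if unknown:
                raise ValueError(f"unknown eye fields {sorted(unknown)}")
            eyes[e["side"]] = EyeLandmarks(
                corner_1=_xyz(e["c1"], "c1"),
                corner_2=_xyz(e["c2"], "c2"),
                surface_point=_xyz(e["surface"], "surface"),
                iris_center=_xyz(e["iris"], "iris"),
                side=e["side"],
            )
    return Frame(
        timestamp=float(rec["t"]),
        person_id=str(rec["person"]),
        head=HeadJoints(**joints),
        eyes=eyes,
    )


def read_frames(path) -> list[Frame]:
    """Read a frame JSONL file; an empty file yields an empty stream."""
    frames = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                frames.append(frame_from_record(json.loads(line)))
            except (ValueError, KeyError, TypeError) as exc:
                raise DataFormatError(str(exc), path=str(path), line=lineno) from exc
    return frames


def write_frames(path, frames) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(json.dumps(frame_to_record(frame)) + "\n")


# ---------------------------------------------------------------------------
# Gaze-estimate JSONL


def estimate_to_record(est: GazeEstimate) -> dict:
    rec: dict = {
        "t": est.timestamp,
        "person": est.person_id,
        "method": est.method,
        "valid": est.valid,
        "fallback": est.fallback,
        "gating_distance": est.gating_distance,
        "sphere_hits": est.sphere_hits,
    }
    if est.ray is not None:
        rec["ray"] = {
            "origin": [float(v) for v in est.ray.origin],
            "direction": [float(v) for v in est.ray.direction],
        }
    if est.plane_hit is not None:
        rec["plane_hit"] = [float(v) for v in est.plane_hit]
    return rec


def estimate_from_record(rec: dict) -> GazeEstimate:
    from .geometry import Ray

    ray = None
    if "ray" in rec:
        ray = Ray(origin=rec["ray"]["origin"], direction=rec["ray"]["direction"])
    return GazeEstimate(
        timestamp=float(rec["t"]),
        person_id=str(rec["person"]),
        method=rec["method"],
        valid=bool(rec["valid"]),
        ray=ray,
        plane_hit=None if "plane_hit" not in rec else np.asarray(rec["plane_hit"], dtype=float),
        sphere_hits=dict(rec.get("sphere_hits", {})),
        gating_distance=rec.get("gating_distance"),
        fallback=bool(rec.get("fallback", False)),
    )


def read_estimates(path) -> list[GazeEstimate]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                out.append(estimate_from_record(json.loads(line)))
            except (ValueError, KeyError, TypeError) as exc:
                raise DataFormatError(str(exc), path=str(path), line=lineno) from exc
    return out


def write_estimates(path, estimates) -> None:
    with open(path, "w") as fh:
        for est in estimates:
            fh.write(json.dumps(estimate_to_record(est)) + "\n")


# ---------------------------------------------------------------------------
# Periods CSV


def read_periods_csv(path) -> list[TimeInterval]:
    """Read a period list; accepts ``start,end`` in mm:ss dialects or ``start_s,end_s``."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    cols = {c.lower(): c for c in df.columns}
    if "start_s" in cols and "end_s" in cols:
        starts, ends = df[cols["start_s"]], df[cols["end_s"]]
        return [TimeInterval(float(s), float(e)) for s, e in zip(starts, ends)]
    if "start" in cols and "end" in cols:
        return [
            TimeInterval(float(parse_mmss(s)), float(parse_mmss(e)))
            for s, e in zip(df[cols["start"]], df[cols["end"]])
        ]
    raise DataFormatError(
        "periods CSV needs columns start/end or start_s/end_s", path=str(path)
    )


def write_periods_csv(path, periods, person_id: str = "", target: str = "") -> None:
    rows = [
        {
            "person_id": person_id,
            "target": target,
            "start_s": int(p.start),
            "end_s": int(p.end),
            "start_mmss": format_mmss(p.start),
            "end_mmss": format_mmss(p.end),
        }
        for p in periods
    ]
    pd.DataFrame(
        rows,
        columns=["person_id", "target", "start_s", "end_s", "start_mmss", "end_mmss"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scene / run configuration (YAML)


def scene_from_dict(d: dict) -> SceneConfig:
    spheres = {}
    for name, spec in (d.get("spheres") or {}).items():
        spheres[name] = HeadSphereSpec(
            radius=float(spec.get("radius", 12.0)),
            person=spec.get("person"),
            center=tuple(spec["center"]) if "center" in spec else None,
        )
    plane_points = d.get("plane_points")
    if plane_points is not None:
        plane_points = tuple(tuple(float(v) for v in p) for p in plane_points)
    return SceneConfig(
        plane_points=plane_points,
        targets={k: v for k, v in (d.get("targets") or {}).items()},
        spheres=spheres,
        gate_cm=float(d.get("gate_cm", 70.0)),
    )


def read_scene_config(path) -> SceneConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    try:
        return scene_from_dict(d)
    except (TypeError, ValueError, KeyError) as exc:
        raise DataFormatError(str(exc), path=str(path)) from exc


@dataclass
class RunConfig:
    """Bundled configuration for a full run; all keys optional with defaults."""

    scene: SceneConfig = field(default_factory=SceneConfig.target_board_default)
    frame_fraction: float = 0.5
    min_duration_s: float = 1.0
    max_gap_s: float = 0.0
    seed: int = 0
    log_level: str = "INFO"


def read_run_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    try:
        scene = scene_from_dict(d["scene"]) if "scene" in d else SceneConfig.target_board_default()
        return RunConfig(
            scene=scene,
            frame_fraction=float(d.get("frame_fraction", 0.5)),
            min_duration_s=float(d.get("min_duration_s", 1.0)),
            max_gap_s=float(d.get("max_gap_s", 0.0)),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise DataFormatError(str(exc), path=str(path)) from exc
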