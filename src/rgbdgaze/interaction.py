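"""Interaction periods from per-frame gaze-target hit streams.

Frame-level hits (gaze ray intersecting the sphere around the other
person's head) are first binned to second resolution — a second counts as a
hit when at least ``frame_fraction`` of its *valid* frames hit — and runs of
hit-seconds then become closed [start, end] intervals in whole seconds,
matching mm:ss-resolution annotation. Mutual gaze is the per-second AND of
the two directed streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

DEFAULT_FRAME_FRACTION = 0.5
DEFAULT_MIN_DURATION_S = 1.0
DEFAULT_MAX_GAP_S = 0.0


@dataclass(frozen=True, order=True)
class TimeInterval:
    """A closed [start, end] period in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InvalidInputError(f"end {self.end} < start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def intersection(self, other: "TimeInterval") -> "TimeInterval | None":
        s, e = max(self.start, other.start), min(self.end, other.end)
        return TimeInterval(s, e) if s <= e else None


@dataclass(frozen=True, eq=False)
class HitStream:
    """Per-frame (timestamp, valid, hit) samples for one gazer -> target pair."""

    timestamps: np.ndarray
    valid: np.ndarray
    hit: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        h = np.asarray(self.hit, dtype=bool)
        if not (t.shape == v.shape == h.shape) or t.ndim != 1:
            raise InvalidInputError("timestamps, valid and hit must be equal-length 1D")
        if t.size and np.any(np.diff(t) < 0):
            raise InvalidInputError("hit-stream timestamps must be monotone")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "valid", v)
        object.__setattr__(self, "hit", h)

    @classmethod
    def from_estimates(cls, estimates, sphere_name: str, person_id: str) -> "HitStream":
        """Build the stream for one gazer and one named sphere from pipeline output."""
        rows = [e for e in estimates if e.person_id == person_id]
        return cls(
            timestamps=np.array([e.timestamp for e in rows], dtype=float),
            valid=np.array([e.valid for e in rows], dtype=bool),
            hit=np.array(
                [e.valid and e.sphere_hits.get(sphere_name, False) for e in rows],
                dtype=bool,
            ),
        )


def binarize_seconds(stream: HitStream, frame_fraction: float = DEFAULT_FRAME_FRACTION) -> np.ndarray:
    """Per-second hit flags over [0, floor(t_max)].

    A second is a hit iff hit-frames / valid-frames in that second is
    >= ``frame_fraction``; seconds with no valid frames are non-hits.
    """
    if not (0 < frame_fraction <= 1):
        raise InvalidInputError("frame_fraction must be in (0, 1]")
    if stream.timestamps.size == 0:
        return np.zeros(0, dtype=bool)
    n_seconds = int(math.floor(stream.timestamps[-1])) + 1
    secs = np.floor(stream.timestamps).astype(int)
    valid_counts = np.bincount(secs[stream.valid], minlength=n_seconds)
    hit_counts = np.bincount(secs[stream.hit], minlength=n_seconds)
    flags = np.zeros(n_seconds, dtype=bool)
    nonzero = valid_counts > 0
    flags[nonzero] = hit_counts[nonzero] >= frame_fraction * valid_counts[nonzero]
    return flags


def extract_periods(
    second_flags,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> list[TimeInterval]:
    """Closed whole-second intervals from per-second hit flags.

    Maximal runs of hit-seconds are found, runs separated by gaps of at most
    ``max_gap_s`` non-hit seconds are merged, and merged runs whose span
    (end - start) is below ``min_duration_s`` are discarded.
    """
    if min_duration_s < 0 or max_gap_s < 0:
        raise InvalidInputError("min_duration_s and max_gap_s must be >= 0")
    flags = np.asarray(second_flags, dtype=bool)
    hit_seconds = np.flatnonzero(flags)
    runs: list[list[int]] = []
    for s in hit_seconds:
        if runs and s - runs[-1][1] - 1 <= max_gap_s:
            runs[-1][1] = int(s)
        else:
            runs.append([int(s), int(s)])
    return [
        TimeInterval(float(a), float(b))
        for a, b in runs
        if b - a >= min_duration_s - 1e-9
    ]


def mutual_gaze(
    hits_a_to_b: HitStream,
    hits_b_to_a: HitStream,
    frame_fraction: float = DEFAULT_FRAME_FRACTION,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> list[TimeInterval]:
    """Periods where both directed gaze streams hit simultaneously (per-second AND)."""
    fa = binarize_seconds(hits_a_to_b, frame_fraction)
    fb = binarize_seconds(hits_b_to_a, frame_fraction)
    if fa.size != fb.size:
        raise InvalidInputError(
            f"streams cover different timelines ({fa.size} vs {fb.size} seconds)"
        )
    return extract_periods(fa & fb, min_duration_s, max_gap_s)
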