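"""Period-level evaluation: interval IoU, off-by-one accuracy, matching.

Detected gaze periods are scored against manually annotated truth periods
with two metrics:

* interval IoU = (min(Et, Ep) - max(St, Sp)) / (max(Et, Ep) - min(St, Sp)),
  clipped to 0 for disjoint intervals, where (St, Et) and (Sp, Ep) are the
  truth and detected endpoints in seconds;
* OBOA (off-by-one accuracy): the indicator that the truth and detected
  *durations* differ by at most one second, averaged over matched periods.

Matching is greedy in descending IoU with each detection used at most once;
truth periods left without any positive-IoU candidate are paired with the
nearest-in-start-time unused detection so that every annotated period
produces a scored row, and leftover detections are reported as false
detections. Session means are taken over the matched truth rows.

Transcribed truth/detection period tables for the two recorded
child-clinician sessions ship with the package (`load_session_periods`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import EmptyInputError, InvalidInputError
from .interaction import TimeInterval

_EPS = 1e-9


@dataclass(frozen=True)
class PeriodMatch:
    """One truth period scored against its paired detection."""

    truth: TimeInterval
    detected: TimeInterval
    overlap: TimeInterval | None
    iou: float
    oboa: int


@dataclass(frozen=True)
class SessionSummary:
    """Session-level means and bookkeeping counts (means over matched rows)."""

    mean_iou: float
    mean_oboa: float
    n_matched: int
    n_missed_truth: int
    n_false_detections: int


def interval_iou(truth: TimeInterval, detected: TimeInterval) -> float:
    """Intersection-over-union of two closed 1D intervals, clipped to [0, 1]."""
    num = min(truth.end, detected.end) - max(truth.start, detected.start)
    den = max(truth.end, detected.end) - min(truth.start, detected.start)
    if den <= 0:
        return 1.0  # two identical zero-length intervals
    return max(num, 0.0) / den


def oboa_indicator(truth: TimeInterval, detected: TimeInterval, tolerance_s: float = 1.0) -> int:
    """1 iff the truth and detected durations differ by at most ``tolerance_s``."""
    return int(abs(truth.duration - detected.duration) <= tolerance_s + _EPS)


def _check_disjoint_sorted(periods: list[TimeInterval], label: str) -> None:
    for a, b in zip(periods, periods[1:]):
        if b.start <= a.end:
            raise InvalidInputError(
                f"{label} periods must be sorted and disjoint; "
                f"[{a.start},{a.end}] vs [{b.start},{b.end}]"
            )


def match_periods(
    truth_list: list[TimeInterval],
    detected_list: list[TimeInterval],
    oboa_tolerance_s: float = 1.0,
) -> tuple[list[PeriodMatch], list[TimeInterval], list[TimeInterval]]:
    """Pair truth periods with detections and score each pair.

    Returns ``(matches, unmatched_truth, false_detections)``; matches are in
    truth order. ``unmatched_truth`` is only non-empty when detections run
    out entirely.
    """
    truth_list = sorted(truth_list)
    detected_list = sorted(detected_list)
    _check_disjoint_sorted(truth_list, "truth")
    _check_disjoint_sorted(detected_list, "detected")

    candidates = []
    for ti, t in enumerate(truth_list):
        for di, d in enumerate(detected_list):
            iou = interval_iou(t, d)
            if iou > 0:
                candidates.append((-iou, t.start, d.start, ti, di))
    candidates.sort()

    truth_to_det: dict[int, int] = {}
    used_det: set[int] = set()
    for _, _, _, ti, di in candidates:
        if ti in truth_to_det or di in used_det:
            continue
        truth_to_det[ti] = di
        used_det.add(di)

    # Nearest-in-time fallback so every truth period yields a scored row.
    unmatched_truth: list[TimeInterval] = []
    for ti, t in enumerate(truth_list):
        if ti in truth_to_det:
            continue
        free = [di for di in range(len(detected_list)) if di not in used_det]
        if not free:
            unmatched_truth.append(t)
            continue
        di = min(free, key=lambda di: (abs(detected_list[di].start - t.start), detected_list[di].start))
        truth_to_det[ti] = di
        used_det.add(di)

    matches = []
    for ti, t in enumerate(truth_list):
        if ti not in truth_to_det:
            continue
        d = detected_list[truth_to_det[ti]]
        matches.append(
            PeriodMatch(
                truth=t,
                detected=d,
                overlap=t.intersection(d),
                iou=interval_iou(t, d),
                oboa=oboa_indicator(t, d, oboa_tolerance_s),
            )
        )
    false_detections = [d for di, d in enumerate(detected_list) if di not in used_det]
    return matches, unmatched_truth, false_detections


def summarize_session(
    matches: list[PeriodMatch],
    unmatched_truth: list[TimeInterval] = (),
    false_detections: list[TimeInterval] = (),
) -> SessionSummary:
    """Arithmetic means of IoU and OBOA over matched rows; rounding is left to presentation."""
    if not matches:
        raise EmptyInputError("cannot summarise an empty match list")
    return SessionSummary(
        mean_iou=sum(m.iou for m in matches) / len(matches),
        mean_oboa=sum(m.oboa for m in matches) / len(matches),
        n_matched=len(matches),
        n_missed_truth=len(unmatched_truth),
        n_false_detections=len(false_detections),
    )


def load_session_periods(session: int, kind: str) -> list[TimeInterval]:
    """Packaged period tables for the two recorded sessions.

    ``session`` is 1 or 2; ``kind`` is ``"truth"`` (manual annotation) or
    ``"detected"`` (the system's output periods).
    """
    from .io import parse_mmss  # local import to avoid a cycle

    if session not in (1, 2):
        raise InvalidInputError(f"session must be 1 or 2, got {session}")
    if kind not in ("truth", "detected"):
        raise InvalidInputError(f"kind must be 'truth' or 'detected', got {kind!r}")
    name = f"session{session}_{kind}.csv"
    with resources.files("rgbdgaze.data").joinpath(name).open("r") as fh:
        df = pd.read_csv(fh)
    return [
        TimeInterval(float(parse_mmss(row.start)), float(parse_mmss(row.end)))
        for row in df.itertuples()
    ]
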