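"""Peri-exercise window segmentation.

Each participant's study timeline is partitioned into five window classes
anchored on the logged exercise sessions:

* ``PRE`` — the 2 h immediately before a session start;
* ``DURING`` — the session itself;
* ``EARLY`` — the 3 h immediately after a session end (early recovery);
* ``LATE`` — from the end of early recovery until the next 08:00 local time,
  or until the next session's PRE window when sessions are closely spaced
  (late recovery);
* ``NONEX`` — all remaining (non-exercise) time.

When windows of different sessions would overlap, the priority order is
``DURING > EARLY > PRE > LATE > NONEX``: a session's early recovery outranks
the following session's pre-exercise window, and only late recovery yields to
a following PRE window.  Intervals are half-open ``[start, end)`` at minute
resolution, so a reading timestamped exactly on a boundary belongs to the
later window.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import SessionRecord

__all__ = [
    "Interval",
    "LabeledWindow",
    "StudySpan",
    "WINDOW_PRIORITY",
    "build_window_partition",
    "label_timepoint",
    "session_interval",
    "windows_frame",
]

PRE_H = timedelta(hours=2)
EARLY_H = timedelta(hours=3)
DEFAULT_MORNING_CUTOFF = time(8, 0)
WINDOW_PRIORITY = ("DURING", "EARLY", "PRE", "LATE", "NONEX")


@dataclass(frozen=True)
class Interval:
    """Half-open time interval [start, end)."""

    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} must precede end {self.end}")

    def __contains__(self, t: datetime) -> bool:
        return self.start <= t < self.end

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


@dataclass(frozen=True)
class LabeledWindow:
    interval: Interval
    window_class: str
    session_id: str | None  # None iff NONEX
    participant_id: str | None = None


@dataclass(frozen=True)
class StudySpan:
    participant_id: str
    interval: Interval


def session_interval(session: SessionRecord) -> Interval:
    """The half-open interval [start, start + duration) of a session."""
    if session.duration_min <= 0:
        raise ValueError(
            f"session {session.session_id}: duration must be positive, "
            f"got {session.duration_min} min"
        )
    return Interval(session.start, session.end)


def _next_morning(t: datetime, cutoff: time) -> datetime:
    """The first cutoff clock time strictly after ``t``."""
    candidate = datetime.combine(t.date(), cutoff)
    if candidate <= t:
        candidate += timedelta(days=1)
    return candidate


def _late_end(
    session: SessionRecord,
    next_session: SessionRecord | None,
    cutoff: time,
) -> datetime:
    early_end = session.end + EARLY_H
    end = _next_morning(early_end, cutoff)
    if next_session is not None:
        end = min(end, next_session.start - PRE_H)
    return end


def label_timepoint(
    t: datetime,
    sessions: Sequence[SessionRecord],
    morning_cutoff: time = DEFAULT_MORNING_CUTOFF,
) -> tuple[str, str | None]:
    """Window class (and owning session) of a single timepoint.

    ``sessions`` must be sorted by start and non-overlapping.  Ties between
    sessions resolve to the nearest qualifying session: the most recent one
    for DURING/EARLY/LATE, the next upcoming one for PRE.
    """
    during = [s for s in sessions if s.start <= t < s.end]
    if during:
        s = max(during, key=lambda s: s.start)
        return "DURING", s.session_id
    early = [s for s in sessions if s.end <= t < s.end + EARLY_H]
    if early:
        s = max(early, key=lambda s: s.end)
        return "EARLY", s.session_id
    pre = [s for s in sessions if s.start - PRE_H <= t < s.start]
    if pre:
        s = min(pre, key=lambda s: s.start)
        return "PRE", s.session_id
    late: list[tuple[datetime, SessionRecord]] = []
    for i, s in enumerate(sessions):
        nxt = sessions[i + 1] if i + 1 < len(sessions) else None
        early_end = s.end + EARLY_H
        if early_end <= t < _late_end(s, nxt, morning_cutoff):
            late.append((early_end, s))
    if late:
        _, s = max(late, key=lambda pair: pair[0])
        return "LATE", s.session_id
    return "NONEX", None


def _validate_sessions(sessions: Sequence[SessionRecord], span: StudySpan) -> None:
    for s in sessions:
        iv = session_interval(s)
        if iv.start < span.interval.start or iv.end > span.interval.end:
            raise ValueError(
                f"session {s.session_id} [{iv.start} .. {iv.end}) lies outside "
                f"study span [{span.interval.start} .. {span.interval.end})"
            )
    for a, b in zip(sessions, sessions[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping sessions for participant {span.participant_id}: "
                f"{a.session_id} and {b.session_id}"
            )


def build_window_partition(
    sessions: Iterable[SessionRecord],
    span: StudySpan,
    morning_cutoff: time = DEFAULT_MORNING_CUTOFF,
) -> list[LabeledWindow]:
    """Partition the study span into labeled windows.

    Returns disjoint, sorted windows whose union is exactly the span; maximal
    runs of equal (class, session) are merged.  Raises on sessions that
    overlap each other or extend beyond the span.
    """
    sessions = sorted(sessions, key=lambda s: s.start)
    _validate_sessions(sessions, span)
    t0, t1 = span.interval.start, span.interval.end

    # every time at which the label can change
    cuts = {t0, t1}
    for i, s in enumerate(sessions):
        nxt = sessions[i + 1] if i + 1 < len(sessions) else None
        early_end = s.end + EARLY_H
        for c in (s.start - PRE_H, s.start, s.end, early_end,
                  _late_end(s, nxt, morning_cutoff)):
            if t0 < c < t1:
                cuts.add(c)
    bounds = sorted(cuts)

    windows: list[LabeledWindow] = []
    for lo, hi in zip(bounds, bounds[1:]):
        wc, sid = label_timepoint(lo, sessions, morning_cutoff)
        if windows and windows[-1].window_class == wc and windows[-1].session_id == sid:
            last = windows[-1]
            windows[-1] = LabeledWindow(
                Interval(last.interval.start, hi), wc, sid, span.participant_id
            )
        else:
            windows.append(LabeledWindow(Interval(lo, hi), wc, sid, span.participant_id))
    return windows


def windows_frame(windows: Iterable[LabeledWindow]) -> pd.DataFrame:
    """Tabular export: participant_id, window_class, start, end, session_id."""
    rows = [
        {
            "participant_id": w.participant_id,
            "window_class": w.window_class,
            "start": w.interval.start.isoformat(),
            "end": w.interval.end.isoformat(),
            "session_id": w.session_id if w.session_id is not None else "",
        }
        for w in windows
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "window_class", "start", "end", "session_id"]
    )


def window_bounds_arrays(
    windows: Sequence[LabeledWindow],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(starts, ends, class codes, session ids) as numpy arrays for fast lookup."""
    from .config import WINDOW_CLASSES

    starts = np.array([np.datetime64(w.interval.start, "s") for w in windows])
    ends = np.array([np.datetime64(w.interval.end, "s") for w in windows])
    classes = np.array([WINDOW_CLASSES.index(w.window_class) for w in windows])
    sids = np.array([w.session_id if w.session_id is not None else "" for w in windows])
    return starts, ends, classes, sids
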