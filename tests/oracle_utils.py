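"""Brute-force per-minute window labeling, independent of the package.

Labels are painted onto a minute grid in reverse priority order
(NONEX, LATE, PRE, EARLY, DURING), with within-class tie-breaks realised by
paint order: chronological for DURING/EARLY/LATE (most recent session wins),
reverse chronological for PRE (next upcoming session wins).  This is a
deliberately different algorithm from the package's interval arithmetic and
serves as the oracle in equivalence tests.
"""

from __future__ import annotations

from datetime import datetime, time, timedelta


def _next_morning(t: datetime, cutoff: time) -> datetime:
    c = datetime.combine(t.date(), cutoff)
    return c if c > t else c + timedelta(days=1)


def minute_labels(
    sessions,
    span_start: datetime,
    span_end: datetime,
    cutoff: time = time(8, 0),
) -> list[tuple[str, str | None]]:
    """(window class, session id) for every minute of [span_start, span_end)."""
    n = int((span_end - span_start).total_seconds() // 60)
    labels: list[tuple[str, str | None]] = [("NONEX", None)] * n

    def paint(t0: datetime, t1: datetime, label: str, sid: str | None) -> None:
        lo = max(0, int((t0 - span_start).total_seconds() // 60))
        hi = min(n, int((t1 - span_start).total_seconds() // 60))
        for m in range(lo, hi):
            labels[m] = (label, sid)

    ordered = sorted(sessions, key=lambda s: s.start)
    for i, s in enumerate(ordered):
        early_end = s.end + timedelta(hours=3)
        late_end = _next_morning(early_end, cutoff)
        if i + 1 < len(ordered):
            late_end = min(late_end, ordered[i + 1].start - timedelta(hours=2))
        paint(early_end, late_end, "LATE", s.session_id)
    for s in reversed(ordered):
        paint(s.start - timedelta(hours=2), s.start, "PRE", s.session_id)
    for s in ordered:
        paint(s.end, s.end + timedelta(hours=3), "EARLY", s.session_id)
    for s in ordered:
        paint(s.start, s.end, "DURING", s.session_id)
    return labels


def expand_partition(windows, span_start: datetime, span_end: datetime):
    """Per-minute (class, session id) implied by an interval partition."""
    n = int((span_end - span_start).total_seconds() // 60)
    out: list[tuple[str, str | None]] = [("?", None)] * n
    for w in windows:
        lo = int((w.interval.start - span_start).total_seconds() // 60)
        hi = int((w.interval.end - span_start).total_seconds() // 60)
        for m in range(lo, hi):
            out[m] = (w.window_class, w.session_id)
    return out
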