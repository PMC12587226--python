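"""Logbook hypoglycemia episode classification and rate aggregation.

Episodes are patient-reported (symptoms and/or an observed low glucose), not
CGM-derived.  Severity follows the consensus thresholds: level 1 is glucose
<70 mg/dL, level 2 is <54 mg/dL.  An episode reported without any glucose
value but with symptoms is classified level 1 by convention and flagged as
imputed rather than silently assigned.

Aggregation is session-first: a session counts as hypoglycemic if it carries
at least one episode (pooling the before/during/after phases), and as level 2
if any episode is level 2.  Stratified rates (activity type, perceived
intensity) use the sessions with a non-missing stratum variable as
denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .config import ACTIVITY_TYPES, BORG_CATEGORIES
from .records import EpisodeReport, SessionRecord

__all__ = ["EpisodeStats", "aggregate_episode_stats", "classify_episode",
           "episode_stats_to_json", "stratified_frame"]

_PHASES = ("before", "during", "after")


def classify_episode(
    session_id: str | None,
    phase: str,
    min_glucose: int | None,
    symptom_class: str,
    detection: str,
    interruption: str,
) -> EpisodeReport:
    """Build a classified :class:`EpisodeReport` from raw logbook fields.

    Level is assigned from the lowest observed glucose (<54 -> level 2, else
    level 1); a missing glucose value yields level 1 with ``level_imputed``
    set.  Raises when the episode has no session linkage.
    """
    if not session_id:
        raise ValueError("episode without session linkage")
    if phase not in _PHASES:
        raise ValueError(f"unknown episode phase {phase!r}")
    if min_glucose is not None:
        level, imputed = (2 if min_glucose < 54 else 1), False
    else:
        level, imputed = 1, True
    return EpisodeReport(
        session_id=session_id,
        phase=phase,
        min_glucose=min_glucose,
        level=level,
        symptom_class=symptom_class,
        detection=detection,
        interruption=interruption,
        level_imputed=imputed,
    )


@dataclass(frozen=True)
class EpisodeStats:
    """Session- and participant-level reported-hypoglycemia rates."""

    n_sessions: int
    n_hypo_sessions: int
    pct_sessions_any: float
    pct_sessions_level1: float  # sessions whose worst episode is level 1
    pct_sessions_level2: float  # sessions with >=1 level-2 episode
    pct_symptomatic_of_hypo_sessions: float
    pct_interrupt_temporary: float  # of hypo sessions
    pct_interrupt_permanent: float
    by_type: dict[str, float]  # % sessions with >=1 episode, per stratum
    n_by_type: dict[str, int]
    by_borg: dict[str, dict[int, float]]  # stratum -> level -> % sessions
    n_by_borg: dict[str, int]
    n_participants: int
    pct_participants_any: float
    pct_participants_level2: float


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else float("nan")


def aggregate_episode_stats(sessions: Sequence[SessionRecord]) -> EpisodeStats:
    """Aggregate reported-episode rates over a cohort of classified sessions."""
    n = len(sessions)
    hypo = [s for s in sessions if s.episodes]
    level2 = [s for s in hypo if any(e.level == 2 for e in s.episodes)]
    level1 = [s for s in hypo if all(e.level == 1 for e in s.episodes)]
    symptomatic = [
        s for s in hypo if any(e.symptom_class != "asymptomatic" for e in s.episodes)
    ]
    interrupted_perm = [
        s for s in hypo if any(e.interruption == "permanent" for e in s.episodes)
    ]
    interrupted_temp = [
        s
        for s in hypo
        if any(e.interruption == "temporary" for e in s.episodes)
        and s not in interrupted_perm
    ]

    by_type: dict[str, float] = {}
    n_by_type: dict[str, int] = {}
    for t in ACTIVITY_TYPES:
        stratum = [s for s in sessions if s.activity_type == t]
        n_by_type[t] = len(stratum)
        by_type[t] = _pct(sum(1 for s in stratum if s.episodes), len(stratum))

    by_borg: dict[str, dict[int, float]] = {}
    n_by_borg: dict[str, int] = {}
    for b in BORG_CATEGORIES:
        stratum = [s for s in sessions if s.borg_category == b]
        n_by_borg[b] = len(stratum)
        worst = [
            2 if any(e.level == 2 for e in s.episodes) else 1
            for s in stratum
            if s.episodes
        ]
        by_borg[b] = {
            1: _pct(sum(1 for w in worst if w == 1), len(stratum)),
            2: _pct(sum(1 for w in worst if w == 2), len(stratum)),
        }

    pids = sorted({s.participant_id for s in sessions})
    pids_hypo = {s.participant_id for s in hypo}
    pids_l2 = {s.participant_id for s in level2}

    return EpisodeStats(
        n_sessions=n,
        n_hypo_sessions=len(hypo),
        pct_sessions_any=_pct(len(hypo), n),
        pct_sessions_level1=_pct(len(level1), n),
        pct_sessions_level2=_pct(len(level2), n),
        pct_symptomatic_of_hypo_sessions=_pct(len(symptomatic), len(hypo)),
        pct_interrupt_temporary=_pct(len(interrupted_temp), len(hypo)),
        pct_interrupt_permanent=_pct(len(interrupted_perm), len(hypo)),
        by_type=by_type,
        n_by_type=n_by_type,
        by_borg=by_borg,
        n_by_borg=n_by_borg,
        n_participants=len(pids),
        pct_participants_any=_pct(len(pids_hypo), len(pids)),
        pct_participants_level2=_pct(len(pids_l2), len(pids)),
    )


def episode_stats_to_json(stats: EpisodeStats) -> str:
    data = {
        "n_sessions": stats.n_sessions,
        "n_hypo_sessions": stats.n_hypo_sessions,
        "pct_sessions_any": stats.pct_sessions_any,
        "pct_sessions_level1": stats.pct_sessions_level1,
        "pct_sessions_level2": stats.pct_sessions_level2,
        "pct_symptomatic_of_hypo_sessions": stats.pct_symptomatic_of_hypo_sessions,
        "pct_interrupt_temporary": stats.pct_interrupt_temporary,
        "pct_interrupt_permanent": stats.pct_interrupt_permanent,
        "by_type": stats.by_type,
        "n_by_type": stats.n_by_type,
        "by_borg": {
            b: {str(l): v for l, v in d.items()} for b, d in stats.by_borg.items()
        },
        "n_by_borg": stats.n_by_borg,
        "n_participants": stats.n_participants,
        "pct_participants_any": stats.pct_participants_any,
        "pct_participants_level2": stats.pct_participants_level2,
    }
    return json.dumps(data, indent=2, allow_nan=True)


def stratified_frame(stats: EpisodeStats) -> pd.DataFrame:
    """Long-format stratified rates (activity type and perceived intensity)."""
    rows = [
        {"stratum": "activity_type", "category": t, "level": "any",
         "n_sessions": stats.n_by_type[t], "pct_sessions": stats.by_type[t]}
        for t in ACTIVITY_TYPES
    ]
    for b in BORG_CATEGORIES:
        for level in (1, 2):
            rows.append(
                {
                    "stratum": "borg",
                    "category": b,
                    "level": str(level),
                    "n_sessions": stats.n_by_borg[b],
                    "pct_sessions": stats.by_borg[b][level],
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "category", "level", "n_sessions",
                                       "pct_sessions"])
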