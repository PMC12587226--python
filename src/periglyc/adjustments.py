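"""Behavioural adjustment classification and guideline-deviation flags.

Users of AID systems are advised to (i) activate a raised temporary glucose
target at least 1 h before exercise, (ii) avoid unannounced snacks in the
hour before a session, and (iii) limit carbohydrate intake during exercise to
at most 20 g at a time.  This module categorizes the per-session logbook
fields against those rules and derives the three boolean deviation flags the
association model consumes.

Boundary conventions: activation exactly 60 min before start counts as early
("at least 1 h"); a single during-exercise intake of exactly 20 g is
compliant; the pre-exercise carbohydrate window is (0, 120] min before start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import TEMP_TARGET_CATEGORIES
from .records import SessionRecord

__all__ = [
    "AdjustmentProfile",
    "AdjustmentSummary",
    "DeviationFlags",
    "adjustments_frame",
    "deviation_flags",
    "profile_from_session",
    "summarize_adjustments",
    "temp_target_category",
]


@dataclass(frozen=True)
class DeviationFlags:
    late_or_no_temp_target: bool
    snack_within_1h_before: bool
    single_intake_gt20g_during: bool

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (
            self.late_or_no_temp_target,
            self.snack_within_1h_before,
            self.single_intake_gt20g_during,
        )


@dataclass(frozen=True)
class AdjustmentProfile:
    session_id: str
    temp_target_category: str
    #: (minutes before start in (0, 120], grams) per pre-exercise intake
    carbs_before: tuple[tuple[int, int], ...]
    #: (minutes after start within the session, grams) per during intake
    carbs_during: tuple[tuple[int, int], ...]
    #: False when the temporary-target logbook block is missing; such
    #: sessions are excluded from temp-target denominators
    data_available: bool = True

    def __post_init__(self) -> None:
        if self.temp_target_category not in TEMP_TARGET_CATEGORIES:
            raise ValueError(f"unknown temp-target category {self.temp_target_category!r}")
        for minutes_before, grams in self.carbs_before:
            if not 0 < minutes_before <= 120:
                raise ValueError(
                    f"session {self.session_id}: pre-exercise intake offset "
                    f"{minutes_before} min outside (0, 120]"
                )
            if grams <= 0:
                raise ValueError(f"session {self.session_id}: grams must be > 0")
        for _, grams in self.carbs_during:
            if grams <= 0:
                raise ValueError(f"session {self.session_id}: grams must be > 0")


@dataclass(frozen=True)
class AdjustmentSummary:
    pct_temp_target_by_category: dict[str, float]
    n_sessions_with_adjustment_data: int
    pct_sessions_carb_before: float
    pct_sessions_carb_during: float
    median_iqr_carb_before: tuple[float, float, float]  # median, q25, q75 (g)
    median_iqr_carb_during: tuple[float, float, float]
    pct_sessions_gt20g_during: float
    n_sessions: int


def temp_target_category(
    activation_offset_min: int | None, session_duration_min: int
) -> str:
    """Classify temporary-target timing relative to session start.

    Offsets are minutes relative to start (negative = before).  Activation at
    or before -60 min is "at least 1 h before"; later activation up to the
    session end is "less than 1 h before or during"; ``None`` is no
    activation.  Activation after the session end is invalid.
    """
    if activation_offset_min is None:
        return "none"
    if activation_offset_min > session_duration_min:
        raise ValueError(
            f"temporary-target activation at {activation_offset_min} min is after "
            f"the session end ({session_duration_min} min)"
        )
    if activation_offset_min <= -60:
        return "activated_ge_1h_before"
    return "activated_lt_1h_or_during"


def profile_from_session(session: SessionRecord) -> AdjustmentProfile:
    """Derive the adjustment profile of one session record."""
    return AdjustmentProfile(
        session_id=session.session_id,
        temp_target_category=temp_target_category(
            session.temp_target_offset_min, session.duration_min
        ),
        carbs_before=tuple((-c.offset_min, c.grams) for c in session.carbs_before),
        carbs_during=tuple((c.offset_min, c.grams) for c in session.carbs_during),
        data_available=session.adjustment_data_available,
    )


def deviation_flags(profile: AdjustmentProfile) -> DeviationFlags:
    """The three guideline-deviation flags of one session."""
    return DeviationFlags(
        late_or_no_temp_target=profile.temp_target_category != "activated_ge_1h_before",
        snack_within_1h_before=any(m < 60 for m, _ in profile.carbs_before),
        single_intake_gt20g_during=any(g > 20 for _, g in profile.carbs_during),
    )


def _median_iqr(per_session_grams: Sequence[float]) -> tuple[float, float, float]:
    if len(per_session_grams) == 0:
        return (float("nan"),) * 3
    med, q25, q75 = np.percentile(per_session_grams, [50, 25, 75])
    return float(med), float(q25), float(q75)


def summarize_adjustments(profiles: Iterable[AdjustmentProfile]) -> AdjustmentSummary:
    """Cohort-level adjustment summary.

    Temporary-target percentages use the complete-case denominator (sessions
    with adjustment data); carbohydrate summaries use all sessions, with
    medians/IQRs over sessions that had any intake.  ``profiles`` must be
    deduplicated by session.
    """
    profiles = list(profiles)
    seen = {p.session_id for p in profiles}
    if len(seen) != len(profiles):
        raise ValueError("profiles must be deduplicated by session")
    n = len(profiles)
    with_data = [p for p in profiles if p.data_available]
    n_data = len(with_data)
    pct_tt = {
        cat: (
            100.0 * sum(p.temp_target_category == cat for p in with_data) / n_data
            if n_data
            else float("nan")
        )
        for cat in TEMP_TARGET_CATEGORIES
    }
    before_totals = [sum(g for _, g in p.carbs_before) for p in profiles if p.carbs_before]
    during_totals = [sum(g for _, g in p.carbs_during) for p in profiles if p.carbs_during]
    gt20 = [deviation_flags(p).single_intake_gt20g_during for p in profiles]
    return AdjustmentSummary(
        pct_temp_target_by_category=pct_tt,
        n_sessions_with_adjustment_data=n_data,
        pct_sessions_carb_before=100.0 * len(before_totals) / n if n else float("nan"),
        pct_sessions_carb_during=100.0 * len(during_totals) / n if n else float("nan"),
        median_iqr_carb_before=_median_iqr(before_totals),
        median_iqr_carb_during=_median_iqr(during_totals),
        pct_sessions_gt20g_during=100.0 * sum(gt20) / n if n else float("nan"),
        n_sessions=n,
    )


def adjustments_frame(profiles: Iterable[AdjustmentProfile]) -> pd.DataFrame:
    """Per-session tabular export with totals and deviation flags."""
    rows = []
    for p in profiles:
        f = deviation_flags(p)
        rows.append(
            {
                "session_id": p.session_id,
                "adjustment_data_available": p.data_available,
                "temp_target_category": p.temp_target_category,
                "total_carbs_before_g": sum(g for _, g in p.carbs_before),
                "total_carbs_during_g": sum(g for _, g in p.carbs_during),
                "late_or_no_temp_target": f.late_or_no_temp_target,
                "snack_within_1h_before": f.snack_within_1h_before,
                "single_intake_gt20g_during": f.single_intake_gt20g_during,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "session_id", "adjustment_data_available", "temp_target_category",
            "total_carbs_before_g", "total_carbs_during_g",
            "late_or_no_temp_target", "snack_within_1h_before",
            "single_intake_gt20g_during",
        ],
    )
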