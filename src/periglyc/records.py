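"""Core data records shared across the pipeline stages.

A cohort is a list of :class:`ParticipantProfile` plus a list of
:class:`SessionRecord` (the logbook) plus one :class:`GlucoseTrace` per
participant (the CGM download).  Timestamps are timezone-naive local clock
time at minute resolution; glucose is integer mg/dL on a nominal 5-minute
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

__all__ = [
    "CarbIntake",
    "EpisodeReport",
    "GlucoseTrace",
    "ParticipantProfile",
    "SessionRecord",
]


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    pump_brand: str
    #: participant-specific baseline log-odds of per-session hypoglycemia
    random_intercept: float = 0.0


@dataclass(frozen=True)
class CarbIntake:
    """One carbohydrate intake event tied to a session.

    ``offset_min`` is minutes relative to session start: negative values are
    pre-exercise intakes (in (-120, 0)), nonnegative values lie within the
    session.
    """

    offset_min: int
    grams: int


@dataclass
class EpisodeReport:
    """One logbook-reported hypoglycemia episode."""

    session_id: str
    phase: str  # before | during | after
    min_glucose: int | None
    level: int  # 1 (<70 mg/dL) or 2 (<54 mg/dL)
    symptom_class: str  # adrenergic | neuroglycopenic | combined | asymptomatic
    detection: str  # symptoms | cgm | capillary
    interruption: str  # none | temporary | permanent
    #: True when the level was assigned by convention (no glucose value)
    level_imputed: bool = False


@dataclass
class SessionRecord:
    """One logged physical-activity session."""

    session_id: str
    participant_id: str
    start: datetime
    duration_min: int
    activity_type: str | None  # None = missing in the logbook
    borg_category: str | None
    #: temporary-target activation time in minutes relative to session start
    #: (negative = before); None = no activation
    temp_target_offset_min: int | None
    #: False when the adjustment (temporary-target) logbook block is missing
    adjustment_data_available: bool = True
    carbs_before: list[CarbIntake] = field(default_factory=list)
    carbs_during: list[CarbIntake] = field(default_factory=list)
    episodes: list[EpisodeReport] = field(default_factory=list)

    @property
    def end(self) -> datetime:
        return self.start + timedelta(minutes=self.duration_min)


@dataclass
class GlucoseTrace:
    """One participant's CGM readings (timestamps strictly increasing)."""

    participant_id: str
    times: np.ndarray  # datetime64[s]
    glucose: np.ndarray  # integer mg/dL in [40, 400]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.glucose = np.asarray(self.glucose)
        if self.times.shape != self.glucose.shape:
            raise ValueError("times and glucose must have equal length")
        if self.times.size > 1 and not (np.diff(self.times).astype(int) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)
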