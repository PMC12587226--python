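"""Seeded synthetic cohort generator.

Emulates the statistical structure of a one-month free-living observational
study of adults with type 1 diabetes on automated insulin delivery (AID)
systems who log unstructured exercise sessions: a paper logbook per session
(type, perceived intensity, temporary-target use, carbohydrate intakes,
reported hypoglycemia episodes) plus a 5-minute CGM trace per participant.

The generator targets *marginals*, not physiology: per-session hypoglycemia
is drawn from a logistic model with a participant random intercept,
type-specific base rates, and optional guideline-deviation effects; CGM
readings are drawn from a band-level Markov process whose stationary
distribution within each peri-exercise window class equals the configured
band occupancy.  There is no insulin-glucose dynamics model.

Reproducibility: one master seed; participant ``i`` uses the independent
substreams ``SeedSequence([seed, i, 0])`` (logbook) and
``SeedSequence([seed, i, 1])`` (CGM), so enlarging the cohort never
reshuffles earlier participants.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats

from .adjustments import deviation_flags, profile_from_session
from .config import (
    ACTIVITY_TYPES,
    BORG_CATEGORIES,
    EPISODE_PHASES,
    INTERRUPTIONS,
    PUMP_BRANDS,
    SYMPTOM_CLASSES,
    TEMP_TARGET_CATEGORIES,
    WINDOW_CLASSES,
    BandOccupancy,
    CohortConfig,
)
from .records import CarbIntake, EpisodeReport, GlucoseTrace, ParticipantProfile, SessionRecord
from .windowing import LabeledWindow, StudySpan, Interval, window_bounds_arrays

__all__ = [
    "COHORT_START",
    "generate_cohort",
    "read_dataset",
    "solve_base_log_odds",
    "study_spans",
    "synthesize_traces",
    "write_dataset",
]

#: nominal first study day (timezone-naive local time; the study never
#: crosses a DST transition because clock time is treated as linear)
COHORT_START = datetime(2024, 4, 1, 0, 0)

_FLAG_NAMES = (
    "late_or_no_temp_target",
    "snack_within_1h_before",
    "single_intake_gt20g_during",
)
# integer glucose sub-ranges of the five bands (inclusive lo, exclusive hi)
_BAND_LO = np.array([40, 54, 70, 181, 251])
_BAND_HI = np.array([54, 70, 181, 251, 401])
_ASYMPT_CGM_PROB = 0.8  # asymptomatic episodes detected by CGM vs capillary


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def solve_base_log_odds(p_marginal: float, sigma: float, n_nodes: int = 40) -> float:
    """Base log-odds ``a`` such that ``E[expit(a + b)] = p`` for b ~ N(0, sigma^2).

    Inverts the random-intercept averaging so configured marginal rates are
    reproduced exactly in expectation.  Uses Gauss-Hermite quadrature.
    """
    if not 0.0 < p_marginal < 1.0:
        raise ValueError("marginal probability must be in (0, 1)")
    if sigma == 0.0:
        return math.log(p_marginal / (1.0 - p_marginal))
    nodes, wts = hermegauss(n_nodes)
    wts = wts / wts.sum()

    def f(a: float) -> float:
        return float(np.sum(wts / (1.0 + np.exp(-(a + sigma * nodes))))) - p_marginal

    return optimize.brentq(f, -30.0, 30.0)


def _participant_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index, stream]))


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float],
                      keys: Sequence[str]) -> str:
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[ParticipantProfile], list[SessionRecord]]:
    """Generate participants and their session logbooks.

    Session start times fall between 07:00 and 21:00, at most one session per
    day, so sessions of one participant never overlap.  Per-session
    hypoglycemia occurrence follows
    ``logit P = alpha(type) + b_i + sum_f delta_f * flag_f`` where ``b_i`` is
    the participant random intercept and the base rates ``alpha(type)`` are
    solved so configured *marginal* rates hold at zero deviation effects.
    """
    config.validate()
    sigma = config.random_intercept_sd
    p_any = {
        t: config.hypo_prob_by_type_and_level[t][1]
        + config.hypo_prob_by_type_and_level[t][2]
        for t in ACTIVITY_TYPES
    }
    alpha = {
        t: (
            -math.inf
            if p <= 0
            else math.inf if p >= 1 else solve_base_log_odds(p, sigma)
        )
        for t, p in p_any.items()
    }
    l2_share = {
        t: (
            config.hypo_prob_by_type_and_level[t][2] / p_any[t]
            if p_any[t] > 0
            else 0.0
        )
        for t in ACTIVITY_TYPES
    }
    delta = config.deviation_effect_log_odds
    dur = config.session_duration_hours
    a_trunc = (dur.min - dur.mean) / dur.sd
    b_trunc = (dur.max - dur.mean) / dur.sd

    participants: list[ParticipantProfile] = []
    sessions: list[SessionRecord] = []
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i, 0)
        pid = f"P{i:03d}"
        brand = _draw_categorical(rng, config.pump_brand_probs, PUMP_BRANDS)
        b_i = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
        # participant-level share of hypo sessions that reach level 2
        q_l2_i = float(rng.beta(config.level2_share_beta_a, 2 * config.level2_share_beta_a))
        participants.append(ParticipantProfile(pid, brand, b_i))

        rate = rng.uniform(*config.sessions_per_week_range)
        n_sessions = int(np.clip(round(rate * config.study_days / 7.0), 1,
                                 config.study_days))
        days = np.sort(rng.choice(config.study_days, size=n_sessions, replace=False))
        start_min = rng.integers(7 * 60, 21 * 60 + 1, size=n_sessions)
        dur_h = stats.truncnorm.rvs(
            a_trunc, b_trunc, loc=dur.mean, scale=dur.sd, size=n_sessions,
            random_state=rng,
        )
        dur_min = np.maximum(np.rint(dur_h * 60).astype(int), 15)

        for k in range(n_sessions):
            sid = f"{pid}-S{k:02d}"
            start = COHORT_START + timedelta(days=int(days[k]), minutes=int(start_min[k]))
            d_min = int(dur_min[k])

            type_true = _draw_categorical(rng, config.activity_type_probs, ACTIVITY_TYPES)
            type_reported = (
                None if rng.random() < config.activity_type_missing_prob else type_true
            )
            borg = _draw_categorical(rng, config.borg_category_probs, BORG_CATEGORIES)
            borg_reported = None if rng.random() < config.borg_missing_prob else borg

            tt_cat = _draw_categorical(
                rng, config.temp_target_category_probs, TEMP_TARGET_CATEGORIES
            )
            if tt_cat == "activated_ge_1h_before":
                tt_offset: int | None = -int(rng.integers(60, 121))
            elif tt_cat == "activated_lt_1h_or_during":
                tt_offset = int(rng.integers(-59, d_min))
            else:
                tt_offset = None
            adj_available = rng.random() >= config.adjustment_missing_prob

            carbs_before: list[CarbIntake] = []
            if rng.random() < config.carb_before_prob:
                grams = max(1, int(round(rng.lognormal(
                    config.carb_before_grams.mu_log, config.carb_before_grams.sigma_log
                ))))
                carbs_before.append(CarbIntake(-int(rng.integers(1, 121)), grams))

            carbs_during: list[CarbIntake] = []
            if rng.random() < config.carb_during_prob:
                total = float(np.clip(rng.lognormal(
                    config.carb_during_grams.mu_log, config.carb_during_grams.sigma_log
                ), 1.0, 200.0))
                if total <= 20.5 or rng.random() < config.carb_during_single_bolus_prob:
                    parts = [total]
                else:
                    m = math.ceil(total / 20.0)
                    parts = [total / m] * m
                offsets = np.sort(rng.choice(d_min, size=len(parts), replace=False))
                carbs_during = [
                    CarbIntake(int(o), max(1, int(round(g))))
                    for o, g in zip(offsets, parts)
                ]

            session = SessionRecord(
                session_id=sid,
                participant_id=pid,
                start=start,
                duration_min=d_min,
                activity_type=type_reported,
                borg_category=borg_reported,
                temp_target_offset_min=tt_offset,
                adjustment_data_available=adj_available,
                carbs_before=carbs_before,
                carbs_during=carbs_during,
            )

            flags = deviation_flags(profile_from_session(session))
            eta = alpha[type_true] + b_i
            for name in _FLAG_NAMES:
                if getattr(flags, name):
                    eta += delta[name]
            if eta == -math.inf:
                p_hypo = 0.0
            elif eta == math.inf:
                p_hypo = 1.0
            else:
                p_hypo = _expit(eta)
            if rng.random() < p_hypo:
                session.episodes.append(
                    _draw_episode(rng, config, sid, l2_share[type_true], q_l2_i)
                )
            sessions.append(session)

    return participants, sessions


def _draw_episode(
    rng: np.random.Generator,
    config: CohortConfig,
    session_id: str,
    base_l2_share: float,
    q_l2_participant: float,
) -> EpisodeReport:
    # participant-level depth propensity q ~ Beta(a, 2a) has mean 1/3; scale
    # it so the population-level share matches the configured one
    share = min(1.0, 3.0 * base_l2_share * q_l2_participant)
    level = 2 if rng.random() < share else 1
    phase = _draw_categorical(rng, config.episode_phase_probs, EPISODE_PHASES)
    symptom = _draw_categorical(rng, config.symptom_class_probs, SYMPTOM_CLASSES)
    if symptom == "asymptomatic":
        detection = "cgm" if rng.random() < _ASYMPT_CGM_PROB else "capillary"
    else:
        detection = "symptoms"
    interruption = _draw_categorical(rng, config.interruption_probs, INTERRUPTIONS)
    if level == 2:
        min_glucose: int | None = int(rng.integers(40, 54))
    else:
        min_glucose = int(rng.integers(54, 70))
    level_imputed = False
    if (
        level == 1
        and symptom != "asymptomatic"
        and rng.random() < config.episode_glucose_missing_prob
    ):
        min_glucose = None
        level_imputed = True
    return EpisodeReport(
        session_id=session_id,
        phase=phase,
        min_glucose=min_glucose,
        level=level,
        symptom_class=symptom,
        detection=detection,
        interruption=interruption,
        level_imputed=level_imputed,
    )


def study_spans(
    config: CohortConfig, participants: Sequence[ParticipantProfile]
) -> list[StudySpan]:
    """One study span per participant: the full study month."""
    interval = Interval(COHORT_START, COHORT_START + timedelta(days=config.study_days))
    return [StudySpan(p.participant_id, interval) for p in participants]


# ---------------------------------------------------------------------------
# CGM synthesis


def synthesize_traces(
    config: CohortConfig,
    sessions: Sequence[SessionRecord],
    windows: Sequence[LabeledWindow],
) -> list[GlucoseTrace]:
    """Draw CGM traces on a 5-minute grid from the labeled partition.

    Within each window the band sequence is a Markov chain that stays in the
    current band with probability ``cgm_persistence`` and otherwise redraws
    from the window class's stationary occupancy; the chain restarts from the
    stationary distribution at every window boundary, so the marginal band
    distribution of *every* reading equals the configured occupancy of its
    window class.  Within-band values are uniform integers.  For a fraction
    ``cgm_missing_session_prob`` of sessions the peri-exercise readings
    (start - 2 h .. end + 3 h) are deleted, emulating failed downloads.
    """
    config.validate()
    occ = np.stack(
        [config.band_occupancy_by_window[wc].as_array() for wc in WINDOW_CLASSES]
    )
    cum = np.cumsum(occ, axis=1)
    cum[:, -1] = 1.0
    rho = config.cgm_persistence

    windows_by_pid: dict[str, list[LabeledWindow]] = {}
    for w in windows:
        windows_by_pid.setdefault(w.participant_id, []).append(w)
    sessions_by_pid: dict[str, list[SessionRecord]] = {}
    for s in sessions:
        sessions_by_pid.setdefault(s.participant_id, []).append(s)

    traces: list[GlucoseTrace] = []
    for i, pid in enumerate(sorted(windows_by_pid)):
        rng = _participant_rng(config.seed, i, 1)
        wins = sorted(windows_by_pid[pid], key=lambda w: w.interval.start)
        starts, ends, codes, _ = window_bounds_arrays(wins)
        t0 = starts[0]
        t1 = ends[-1]
        n = int((t1 - t0).astype("timedelta64[s]").astype(int) // 300)
        times = t0 + np.arange(n) * np.timedelta64(300, "s")

        idx = np.searchsorted(starts, times, side="right") - 1
        if (idx < 0).any() or (times >= ends[idx]).any():
            raise RuntimeError(
                f"window partition for participant {pid} does not cover its grid"
            )
        code = codes[idx]

        miss = rng.random(len(sessions_by_pid.get(pid, []))) < config.cgm_missing_session_prob
        u = rng.random(n)
        band_fresh = (u[:, None] >= cum[code]).sum(axis=1)
        if rho > 0.0:
            keep = rng.random(n) < rho
            keep[0] = False
            keep[np.r_[False, np.diff(idx) != 0]] = False
            src = np.where(keep, 0, np.arange(n))
            band = band_fresh[np.maximum.accumulate(src)]
        else:
            band = band_fresh
        glucose = rng.integers(_BAND_LO[band], _BAND_HI[band])

        mask = np.ones(n, dtype=bool)
        for s, m in zip(sessions_by_pid.get(pid, []), miss):
            if m:
                lo = np.datetime64(s.start - timedelta(hours=2), "s")
                hi = np.datetime64(s.end + timedelta(hours=3), "s")
                mask &= ~((times >= lo) & (times < hi))
        traces.append(GlucoseTrace(pid, times[mask], glucose[mask]))
    return traces


# ---------------------------------------------------------------------------
# dataset I/O (plain CSV, lossless round-trip)


def write_dataset(
    participants: Sequence[ParticipantProfile],
    sessions: Sequence[SessionRecord],
    traces: Sequence[GlucoseTrace],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write participants/sessions/episodes/carbs/cgm CSVs into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv"
             for name in ("participants", "sessions", "episodes", "carbs", "cgm")}

    pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "pump_brand": p.pump_brand,
                "random_intercept": repr(p.random_intercept),
            }
            for p in participants
        ],
        columns=["participant_id", "pump_brand", "random_intercept"],
    ).to_csv(paths["participants"], index=False)

    pd.DataFrame(
        [
            {
                "session_id": s.session_id,
                "participant_id": s.participant_id,
                "start": s.start.isoformat(),
                "duration_min": s.duration_min,
                "activity_type": s.activity_type or "",
                "borg_category": s.borg_category or "",
                "temp_target_offset_min": (
                    "" if s.temp_target_offset_min is None else s.temp_target_offset_min
                ),
                "adjustment_data_available": s.adjustment_data_available,
            }
            for s in sessions
        ],
        columns=[
            "session_id", "participant_id", "start", "duration_min",
            "activity_type", "borg_category", "temp_target_offset_min",
            "adjustment_data_available",
        ],
    ).to_csv(paths["sessions"], index=False)

    pd.DataFrame(
        [
            {
                "session_id": e.session_id,
                "phase": e.phase,
                "min_glucose": "" if e.min_glucose is None else e.min_glucose,
                "level": e.level,
                "symptom_class": e.symptom_class,
                "detection": e.detection,
                "interruption": e.interruption,
                "level_imputed": e.level_imputed,
            }
            for s in sessions
            for e in s.episodes
        ],
        columns=[
            "session_id", "phase", "min_glucose", "level", "symptom_class",
            "detection", "interruption", "level_imputed",
        ],
    ).to_csv(paths["episodes"], index=False)

    pd.DataFrame(
        [
            {
                "session_id": s.session_id,
                "timing": timing,
                "offset_min": c.offset_min,
                "grams": c.grams,
            }
            for s in sessions
            for timing, intakes in (("before", s.carbs_before), ("during", s.carbs_during))
            for c in intakes
        ],
        columns=["session_id", "timing", "offset_min", "grams"],
    ).to_csv(paths["carbs"], index=False)

    frames = [
        pd.DataFrame(
            {
                "participant_id": tr.participant_id,
                "timestamp": np.datetime_as_string(tr.times, unit="s"),
                "glucose_mg_dl": tr.glucose,
            }
        )
        for tr in traces
    ]
    cgm = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["participant_id", "timestamp", "glucose_mg_dl"])
    )
    cgm.to_csv(paths["cgm"], index=False)
    return paths


def read_dataset(
    data_dir: str | Path,
) -> tuple[list[ParticipantProfile], list[SessionRecord], list[GlucoseTrace]]:
    """Read a dataset written by :func:`write_dataset` (lossless inverse)."""
    d = Path(data_dir)
    opts = dict(dtype=str, keep_default_na=False)

    pdf = pd.read_csv(d / "participants.csv", **opts)
    participants = [
        ParticipantProfile(r.participant_id, r.pump_brand, float(r.random_intercept))
        for r in pdf.itertuples()
    ]

    episodes_by_sid: dict[str, list[EpisodeReport]] = {}
    for r in pd.read_csv(d / "episodes.csv", **opts).itertuples():
        episodes_by_sid.setdefault(r.session_id, []).append(
            EpisodeReport(
                session_id=r.session_id,
                phase=r.phase,
                min_glucose=None if r.min_glucose == "" else int(r.min_glucose),
                level=int(r.level),
                symptom_class=r.symptom_class,
                detection=r.detection,
                interruption=r.interruption,
                level_imputed=r.level_imputed == "True",
            )
        )
    carbs_by_sid: dict[str, dict[str, list[CarbIntake]]] = {}
    for r in pd.read_csv(d / "carbs.csv", **opts).itertuples():
        carbs_by_sid.setdefault(r.session_id, {"before": [], "during": []})[
            r.timing
        ].append(CarbIntake(int(r.offset_min), int(r.grams)))

    sessions = []
    for r in pd.read_csv(d / "sessions.csv", **opts).itertuples():
        carbs = carbs_by_sid.get(r.session_id, {"before": [], "during": []})
        sessions.append(
            SessionRecord(
                session_id=r.session_id,
                participant_id=r.participant_id,
                start=datetime.fromisoformat(r.start),
                duration_min=int(r.duration_min),
                activity_type=r.activity_type or None,
                borg_category=r.borg_category or None,
                temp_target_offset_min=(
                    None if r.temp_target_offset_min == "" else int(r.temp_target_offset_min)
                ),
                adjustment_data_available=r.adjustment_data_available == "True",
                carbs_before=carbs["before"],
                carbs_during=carbs["during"],
                episodes=episodes_by_sid.get(r.session_id, []),
            )
        )

    cgm = pd.read_csv(d / "cgm.csv", **opts)
    traces = []
    for pid, grp in cgm.groupby("participant_id", sort=True):
        traces.append(
            GlucoseTrace(
                str(pid),
                grp["timestamp"].to_numpy(dtype="datetime64[s]"),
                grp["glucose_mg_dl"].to_numpy(dtype=int),
            )
        )
    return participants, sessions, traces
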