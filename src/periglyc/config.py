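"""Cohort configuration for the synthetic generator.

:class:`CohortConfig` is the single source of truth for every distributional
assumption the generator makes: cohort size, session scheduling, the
window-conditional glucose band occupancies the CGM process targets, and the
logbook marginals (hypoglycemia rates, temporary-target use, carbohydrate
intake).  The defaults encode the marginals of an 86-participant, one-month
observational cohort of AID users logging ~2.6 unstructured exercise sessions
per week; see ``docs/methods.md`` for the provenance of each number.

Configs round-trip through YAML/JSON with field names preserved, so a study
calibration can be shipped as a plain text file.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ACTIVITY_TYPES",
    "BORG_CATEGORIES",
    "WINDOW_CLASSES",
    "BandOccupancy",
    "CohortConfig",
    "ConfigError",
    "LognormalSpec",
    "TruncNormalSpec",
    "default_config",
    "load_config",
    "save_config",
]

ACTIVITY_TYPES = ("aerobic", "anaerobic", "mixed")
BORG_CATEGORIES = ("nothing", "low", "moderate", "high")
SYMPTOM_CLASSES = ("adrenergic", "neuroglycopenic", "combined", "asymptomatic")
INTERRUPTIONS = ("none", "temporary", "permanent")
TEMP_TARGET_CATEGORIES = (
    "activated_ge_1h_before",
    "activated_lt_1h_or_during",
    "none",
)
PUMP_BRANDS = ("Medtronic", "Tandem", "Ypsomed")
WINDOW_CLASSES = ("PRE", "DURING", "EARLY", "LATE", "NONEX")
EPISODE_PHASES = ("before", "during", "after")

_PROB_TOL = 1e-9


class ConfigError(ValueError):
    """Invalid cohort configuration; ``field`` names the offending entry."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class BandOccupancy:
    """Stationary probabilities of the five glucose bands within one window class.

    Bands follow the consensus CGM thresholds: <54, 54-69, 70-180, 181-250,
    and >250 mg/dL.
    """

    p_lt54: float
    p_54_69: float
    p_70_180: float
    p_181_250: float
    p_gt250: float

    def as_array(self):
        import numpy as np

        return np.array(
            [self.p_lt54, self.p_54_69, self.p_70_180, self.p_181_250, self.p_gt250]
        )

    def validate(self, name: str) -> None:
        vals = [self.p_lt54, self.p_54_69, self.p_70_180, self.p_181_250, self.p_gt250]
        if any(v < 0 for v in vals):
            raise ConfigError(name, "band occupancies must be nonnegative")
        if abs(sum(vals) - 1.0) > _PROB_TOL:
            raise ConfigError(name, f"band occupancies sum to {sum(vals)!r}, not 1")


@dataclass(frozen=True)
class TruncNormalSpec:
    """Normal(mean, sd) truncated to [min, max]; units set by context."""

    mean: float
    sd: float
    min: float
    max: float

    def validate(self, name: str) -> None:
        if self.sd <= 0:
            raise ConfigError(name, "sd must be > 0")
        if not self.min < self.max:
            raise ConfigError(name, "min must be < max")


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal specified by its median and the SD of log values."""

    median: float
    sigma_log: float

    @property
    def mu_log(self) -> float:
        return math.log(self.median)

    def validate(self, name: str) -> None:
        if self.median <= 0:
            raise ConfigError(name, "median must be > 0")
        if self.sigma_log <= 0:
            raise ConfigError(name, "sigma_log must be > 0")


def _check_probs(name: str, probs: Mapping[str, float], keys: tuple[str, ...]) -> None:
    if set(probs) != set(keys):
        raise ConfigError(name, f"keys must be exactly {sorted(keys)}")
    if any(v < 0 for v in probs.values()):
        raise ConfigError(name, "probabilities must be nonnegative")
    total = sum(probs.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ConfigError(name, f"probabilities sum to {total!r}, not 1")


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(name, f"must be a probability in [0, 1], got {p!r}")


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_participants: int = 86
    study_days: int = 30
    #: uniform weekly session rate (continuous); inclusion floor is 2/week
    sessions_per_week_range: tuple[float, float] = (2.0, 3.2)
    session_duration_hours: TruncNormalSpec = field(
        default_factory=lambda: TruncNormalSpec(mean=1.5, sd=1.1, min=0.25, max=6.0)
    )
    activity_type_probs: dict[str, float] = field(
        default_factory=lambda: {
            "aerobic": 0.73 / 0.97,
            "anaerobic": 0.09 / 0.97,
            "mixed": 0.15 / 0.97,
        }
    )
    borg_category_probs: dict[str, float] = field(
        default_factory=lambda: {
            "nothing": 0.02 / 0.99,
            "low": 0.27 / 0.99,
            "moderate": 0.61 / 0.99,
            "high": 0.09 / 0.99,
        }
    )
    pump_brand_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Medtronic": 39 / 86,
            "Tandem": 25 / 86,
            "Ypsomed": 22 / 86,
        }
    )
    band_occupancy_by_window: dict[str, BandOccupancy] = field(
        default_factory=lambda: {
            "PRE": BandOccupancy(0.003, 0.007, 0.73, 0.21, 0.05),
            "DURING": BandOccupancy(0.02, 0.04, 0.69, 0.20, 0.05),
            "EARLY": BandOccupancy(0.017, 0.033, 0.69, 0.21, 0.05),
            "LATE": BandOccupancy(0.013, 0.027, 0.74, 0.17, 0.05),
            "NONEX": BandOccupancy(0.01, 0.02, 0.73, 0.19, 0.05),
        }
    )
    #: stay-probability of the per-window band process on the 5-min grid.
    #: Any value in [0, 1) leaves the per-class marginals exactly at the
    #: configured occupancies; 0 makes readings conditionally independent.
    cgm_persistence: float = 0.0
    #: fraction of sessions whose peri-exercise CGM (start-2h .. end+3h)
    #: could not be retrieved (714 of 954 sessions had usable CGM)
    cgm_missing_session_prob: float = 0.25
    #: marginal per-session probability of a reported episode of each level,
    #: by (true) activity type; level shares are 2:1 in favour of level 1
    hypo_prob_by_type_and_level: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "aerobic": {1: 0.20 * 2 / 3, 2: 0.20 / 3},
            "anaerobic": {1: 0.12 * 2 / 3, 2: 0.12 / 3},
            "mixed": {1: 0.21 * 2 / 3, 2: 0.21 / 3},
        }
    )
    #: participant-level dispersion of the level-2 share of hypo sessions:
    #: share_i ~ Beta(a, 2a), mean 1/3.  Calibrated so 38% of participants
    #: see >=1 level-2 episode over the month.
    level2_share_beta_a: float = 0.2763
    symptom_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "adrenergic": 0.10,
            "neuroglycopenic": 0.13,
            "combined": 0.42,
            "asymptomatic": 0.35,
        }
    )
    interruption_probs: dict[str, float] = field(
        default_factory=lambda: {"none": 0.69, "temporary": 0.19, "permanent": 0.12}
    )
    temp_target_category_probs: dict[str, float] = field(
        default_factory=lambda: {
            "activated_ge_1h_before": 0.27,
            "activated_lt_1h_or_during": 0.46,
            "none": 0.27,
        }
    )
    carb_before_prob: float = 0.36
    carb_during_prob: float = 0.27
    carb_before_grams: LognormalSpec = field(
        default_factory=lambda: LognormalSpec(median=20.0, sigma_log=0.513831)
    )
    carb_during_grams: LognormalSpec = field(
        default_factory=lambda: LognormalSpec(median=25.5, sigma_log=0.679247)
    )
    #: probability that a during-exercise total >20 g is taken as one bolus
    #: rather than split into <=20 g portions
    carb_during_single_bolus_prob: float = 0.5916
    deviation_effect_log_odds: dict[str, float] = field(
        default_factory=lambda: {
            "late_or_no_temp_target": 0.0,
            "snack_within_1h_before": 0.0,
            "single_intake_gt20g_during": 0.0,
        }
    )
    random_intercept_sd: float = 0.5
    #: fraction of sessions with the temporary-target logbook block missing
    #: (824 of 954 sessions had adjustment data)
    adjustment_missing_prob: float = 130 / 954
    activity_type_missing_prob: float = 0.035
    borg_missing_prob: float = 0.01
    episode_phase_probs: dict[str, float] = field(
        default_factory=lambda: {"before": 0.10, "during": 0.60, "after": 0.30}
    )
    #: chance a symptomatic level-1 episode is logged without a glucose value
    episode_glucose_missing_prob: float = 0.05
    seed: int = 20240315

    # ------------------------------------------------------------------
    def validate(self) -> "CohortConfig":
        """Check all invariants; raise :class:`ConfigError` naming the field."""
        if self.n_participants < 1:
            raise ConfigError("n_participants", "must be >= 1")
        if self.study_days < 1:
            raise ConfigError("study_days", "must be >= 1")
        lo, hi = self.sessions_per_week_range
        if not (0 < lo <= hi):
            raise ConfigError("sessions_per_week_range", "need 0 < low <= high")
        self.session_duration_hours.validate("session_duration_hours")
        _check_probs("activity_type_probs", self.activity_type_probs, ACTIVITY_TYPES)
        _check_probs("borg_category_probs", self.borg_category_probs, BORG_CATEGORIES)
        _check_probs("pump_brand_probs", self.pump_brand_probs, PUMP_BRANDS)
        if set(self.band_occupancy_by_window) != set(WINDOW_CLASSES):
            raise ConfigError(
                "band_occupancy_by_window",
                f"keys must be exactly {sorted(WINDOW_CLASSES)}",
            )
        for wc, occ in self.band_occupancy_by_window.items():
            occ.validate(f"band_occupancy_by_window[{wc}]")
        if not 0.0 <= self.cgm_persistence < 1.0:
            raise ConfigError("cgm_persistence", "must be in [0, 1)")
        _check_prob("cgm_missing_session_prob", self.cgm_missing_session_prob)
        if set(self.hypo_prob_by_type_and_level) != set(ACTIVITY_TYPES):
            raise ConfigError(
                "hypo_prob_by_type_and_level",
                f"keys must be exactly {sorted(ACTIVITY_TYPES)}",
            )
        for t, levels in self.hypo_prob_by_type_and_level.items():
            if set(levels) != {1, 2}:
                raise ConfigError(
                    "hypo_prob_by_type_and_level", f"[{t}] needs levels {{1, 2}}"
                )
            total = levels[1] + levels[2]
            if not (0.0 <= levels[1] and 0.0 <= levels[2] and total <= 1.0):
                raise ConfigError(
                    "hypo_prob_by_type_and_level",
                    f"[{t}] level probabilities must be >=0 with sum <=1",
                )
        if self.level2_share_beta_a <= 0:
            raise ConfigError("level2_share_beta_a", "must be > 0")
        _check_probs("symptom_class_probs", self.symptom_class_probs, SYMPTOM_CLASSES)
        _check_probs("interruption_probs", self.interruption_probs, INTERRUPTIONS)
        _check_probs(
            "temp_target_category_probs",
            self.temp_target_category_probs,
            TEMP_TARGET_CATEGORIES,
        )
        _check_prob("carb_before_prob", self.carb_before_prob)
        _check_prob("carb_during_prob", self.carb_during_prob)
        self.carb_before_grams.validate("carb_before_grams")
        self.carb_during_grams.validate("carb_during_grams")
        _check_prob("carb_during_single_bolus_prob", self.carb_during_single_bolus_prob)
        expected_flags = {
            "late_or_no_temp_target",
            "snack_within_1h_before",
            "single_intake_gt20g_during",
        }
        if set(self.deviation_effect_log_odds) != expected_flags:
            raise ConfigError(
                "deviation_effect_log_odds", f"keys must be exactly {sorted(expected_flags)}"
            )
        if self.random_intercept_sd < 0:
            raise ConfigError("random_intercept_sd", "must be >= 0")
        _check_prob("adjustment_missing_prob", self.adjustment_missing_prob)
        _check_prob("activity_type_missing_prob", self.activity_type_missing_prob)
        _check_prob("borg_missing_prob", self.borg_missing_prob)
        _check_probs("episode_phase_probs", self.episode_phase_probs, EPISODE_PHASES)
        _check_prob("episode_glucose_missing_prob", self.episode_glucose_missing_prob)
        if not isinstance(self.seed, int):
            raise ConfigError("seed", "must be an integer")
        return self


def default_config(**overrides: Any) -> CohortConfig:
    """The calibrated default cohort, with optional field overrides."""
    cfg = dataclasses.replace(CohortConfig(), **overrides)
    return cfg.validate()


# ---------------------------------------------------------------------------
# serialisation


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, (BandOccupancy, TruncNormalSpec, LognormalSpec)):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def config_to_dict(cfg: CohortConfig) -> dict[str, Any]:
    out = {}
    for f in dataclasses.fields(cfg):
        out[f.name] = _to_plain(getattr(cfg, f.name))
    return out


def config_from_dict(data: Mapping[str, Any]) -> CohortConfig:
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown configuration field")
    kwargs: dict[str, Any] = dict(data)
    if "sessions_per_week_range" in kwargs:
        kwargs["sessions_per_week_range"] = tuple(kwargs["sessions_per_week_range"])
    if "session_duration_hours" in kwargs and isinstance(
        kwargs["session_duration_hours"], Mapping
    ):
        kwargs["session_duration_hours"] = TruncNormalSpec(**kwargs["session_duration_hours"])
    for name in ("carb_before_grams", "carb_during_grams"):
        if name in kwargs and isinstance(kwargs[name], Mapping):
            kwargs[name] = LognormalSpec(**kwargs[name])
    if "band_occupancy_by_window" in kwargs:
        kwargs["band_occupancy_by_window"] = {
            wc: occ if isinstance(occ, BandOccupancy) else BandOccupancy(**occ)
            for wc, occ in kwargs["band_occupancy_by_window"].items()
        }
    if "hypo_prob_by_type_and_level" in kwargs:
        kwargs["hypo_prob_by_type_and_level"] = {
            t: {int(lvl): p for lvl, p in levels.items()}
            for t, levels in kwargs["hypo_prob_by_type_and_level"].items()
        }
    return CohortConfig(**kwargs).validate()


def load_config(path: str | Path) -> CohortConfig:
    """Read a YAML or JSON config whose keys mirror :class:`CohortConfig`."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data)


def save_config(cfg: CohortConfig, path: str | Path) -> None:
    data = config_to_dict(cfg)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
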