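"""Glucose band metrics (TBR / TIR / TAR) pooled by window class.

The five consensus bands are <54, 54-69, 70-180, 181-250 and >250 mg/dL;
time below range (TBR) is the share of readings <70 (level 2: <54), time in
range (TIR) is 70-180 inclusive, time above range (TAR) is >180 (level 2:
>250).  Time share is approximated by reading share on the nominal 5-minute
grid; CGM gaps are not interpolated.

Default pooling is reading-weighted across all time of a window class (every
reading counts once, across participants and sessions); an unweighted
per-participant mean is exposed as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import WINDOW_CLASSES
from .records import GlucoseTrace
from .windowing import LabeledWindow, window_bounds_arrays

__all__ = [
    "BAND_LABELS",
    "BandDefinition",
    "DEFAULT_BANDS",
    "WindowMetrics",
    "band_of",
    "compute_window_metrics",
    "metrics_table",
]

logger = logging.getLogger(__name__)

BAND_LABELS = ("<54", "54-69", "70-180", "181-250", ">250")
_BAND_COLS = ("pct_lt54", "pct_54_69", "pct_70_180", "pct_181_250", "pct_gt250")
GLUCOSE_MIN, GLUCOSE_MAX = 40, 400
# upper edges; bands are <54 | [54,70) | [70,181) | [181,251) | >=251, which
# on integer readings equals the printed <54 / 54-69 / 70-180 / 181-250 / >250
_BAND_EDGES = np.array([54, 70, 181, 251])


@dataclass(frozen=True)
class BandDefinition:
    """Ordered, contiguous glucose bands covering [40, 400] mg/dL."""

    bands: tuple[tuple[str, int, int], ...]  # (label, lower, upper), inclusive

    def __post_init__(self) -> None:
        lo = GLUCOSE_MIN
        for label, b_lo, b_hi in self.bands:
            if b_lo != lo or b_hi < b_lo:
                raise ValueError(f"bands must be contiguous; problem at {label!r}")
            lo = b_hi + 1
        if lo != GLUCOSE_MAX + 1:
            raise ValueError("bands must cover [40, 400] mg/dL")


DEFAULT_BANDS = BandDefinition(
    (
        ("<54", 40, 53),
        ("54-69", 54, 69),
        ("70-180", 70, 180),
        ("181-250", 181, 250),
        (">250", 251, 400),
    )
)


@dataclass(frozen=True)
class WindowMetrics:
    """Pooled band percentages of one window class."""

    window_class: str
    n_readings: int
    hours: float
    pct_by_band: dict[str, float]  # NaN-valued when n_readings == 0
    tbr_total_pct: float
    tir_pct: float
    tar_total_pct: float


def band_of(glucose: float) -> str:
    """Band label of a single glucose value in [40, 400] mg/dL."""
    if not GLUCOSE_MIN <= glucose <= GLUCOSE_MAX:
        raise ValueError(f"glucose {glucose} mg/dL outside the sensor range [40, 400]")
    return BAND_LABELS[int(np.searchsorted(_BAND_EDGES, glucose, side="right"))]


def _band_codes(glucose: np.ndarray) -> np.ndarray:
    bad = (glucose < GLUCOSE_MIN) | (glucose > GLUCOSE_MAX)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} glucose values outside the sensor range [40, 400]"
        )
    return np.searchsorted(_BAND_EDGES, glucose, side="right")


def compute_window_metrics(
    traces: Iterable[GlucoseTrace],
    windows: Sequence[LabeledWindow],
    pooling: str = "readings",
) -> tuple[dict[str, WindowMetrics], int]:
    """Band percentages per window class, plus the count of excluded readings.

    Every reading is assigned to the unique window containing its timestamp;
    readings outside the labeled span are excluded (logged as a warning).
    ``pooling`` is ``"readings"`` (reading-weighted, default) or
    ``"participant_mean"`` (unweighted mean of per-participant percentages).

    Window classes with no readings are reported with ``n_readings = 0`` and
    NaN percentages rather than zeros.
    """
    if pooling not in ("readings", "participant_mean"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    windows_by_pid: dict[str, list[LabeledWindow]] = {}
    for w in windows:
        windows_by_pid.setdefault(w.participant_id, []).append(w)

    counts_total = np.zeros((5, 5), dtype=np.int64)  # class x band
    per_participant: list[np.ndarray] = []
    excluded = 0
    for tr in traces:
        wins = sorted(
            windows_by_pid.get(tr.participant_id, []), key=lambda w: w.interval.start
        )
        if not wins:
            excluded += len(tr)
            continue
        starts, ends, codes, _ = window_bounds_arrays(wins)
        times = tr.times
        idx = np.searchsorted(starts, times, side="right") - 1
        inside = (idx >= 0) & (times < ends[np.clip(idx, 0, len(wins) - 1)])
        excluded += int((~inside).sum())
        cls = codes[idx[inside]]
        band = _band_codes(np.asarray(tr.glucose)[inside])
        counts = np.bincount(cls * 5 + band, minlength=25).reshape(5, 5)
        counts_total += counts
        per_participant.append(counts)
    if excluded:
        logger.warning("%d readings fall outside the labeled span; excluded", excluded)

    metrics: dict[str, WindowMetrics] = {}
    for ci, wc in enumerate(WINDOW_CLASSES):
        n = int(counts_total[ci].sum())
        if n == 0:
            pct = np.full(5, np.nan)
        elif pooling == "readings":
            pct = 100.0 * counts_total[ci] / n
        else:
            shares = [
                100.0 * c[ci] / c[ci].sum() for c in per_participant if c[ci].sum() > 0
            ]
            pct = np.mean(shares, axis=0)
        metrics[wc] = WindowMetrics(
            window_class=wc,
            n_readings=n,
            hours=n * 5.0 / 60.0,
            pct_by_band=dict(zip(BAND_LABELS, (float(x) for x in pct))),
            tbr_total_pct=float(pct[0] + pct[1]),
            tir_pct=float(pct[2]),
            tar_total_pct=float(pct[3] + pct[4]),
        )
    return metrics, excluded


def metrics_table(metrics: Mapping[str, WindowMetrics]) -> pd.DataFrame:
    """One row per window class; full-precision values for CSV export."""
    rows = []
    for wc in WINDOW_CLASSES:
        if wc not in metrics:
            continue
        m = metrics[wc]
        row = {"window_class": wc, "n_readings": m.n_readings, "hours": m.hours}
        row.update(dict(zip(_BAND_COLS, (m.pct_by_band[b] for b in BAND_LABELS))))
        row.update(
            tbr_total=m.tbr_total_pct, tir=m.tir_pct, tar_total=m.tar_total_pct
        )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["window_class", "n_readings", "hours", *_BAND_COLS,
                 "tbr_total", "tir", "tar_total"],
    )


def render_console(table: pd.DataFrame) -> str:
    """Console view with percentages rounded to whole numbers."""
    view = table.copy()
    for col in view.columns:
        if col.startswith("pct") or col in ("tbr_total", "tir", "tar_total"):
            view[col] = view[col].round(0)
        if col == "hours":
            view[col] = view[col].round(1)
    return view.to_string(index=False)
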