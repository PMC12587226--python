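from __future__ import annotations

import pytest

from periglyc.config import default_config
from periglyc.synthetic_data import generate_cohort, study_spans, synthesize_traces
from periglyc.windowing import build_window_partition


def run_pipeline(cfg):
    """Generate a cohort and everything derived from it (shared helper)."""
    participants, sessions = generate_cohort(cfg)
    spans = study_spans(cfg, participants)
    by_pid = {p.participant_id: [] for p in participants}
    for s in sessions:
        by_pid[s.participant_id].append(s)
    windows = []
    for span in spans:
        windows.extend(build_window_partition(by_pid[span.participant_id], span))
    traces = synthesize_traces(cfg, sessions, windows)
    return participants, sessions, windows, traces


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant, 10-day cohort: fast but structurally complete."""
    cfg = default_config(n_participants=12, study_days=10, seed=424242)
    return cfg, *run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full calibrated default cohort (86 participants, 30 days)."""
    cfg = default_config()
    return cfg, *run_pipeline(cfg)
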