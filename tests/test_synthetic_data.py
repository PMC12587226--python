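"""Generator contracts: determinism, degenerate configs, calibration recovery."""

from __future__ import annotations

import hashlib
from datetime import time, timedelta
from pathlib import Path

import numpy as np
import pytest

from periglyc.config import default_config
from periglyc.synthetic_data import (
    COHORT_START,
    generate_cohort,
    read_dataset,
    solve_base_log_odds,
    study_spans,
    synthesize_traces,
    write_dataset,
)
from periglyc.windowing import build_window_partition, window_bounds_arrays

from conftest import run_pipeline


def _dir_hashes(d: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(d.iterdir())
    }


class TestGenerateCohort:
    def test_cohort_scale_matches_defaults(self, default_cohort):
        cfg, participants, sessions, windows, traces = default_cohort
        assert len(participants) == 86
        # ~954 sessions: weekly rate in [2, 3.2] over 30 days
        assert 850 <= len(sessions) <= 1070
        for s in sessions:
            assert time(7, 0) <= s.start.time() <= time(21, 0)
            assert s.duration_min >= 15

    def test_zero_hypo_rate_yields_no_episodes(self):
        cfg = default_config(
            n_participants=8,
            study_days=10,
            hypo_prob_by_type_and_level={
                t: {1: 0.0, 2: 0.0} for t in ("aerobic", "anaerobic", "mixed")
            },
            seed=5,
        )
        _, sessions = generate_cohort(cfg)
        assert sessions and all(not s.episodes for s in sessions)

    def test_degenerate_type_distribution(self):
        cfg = default_config(
            n_participants=8,
            study_days=10,
            activity_type_probs={"aerobic": 1.0, "anaerobic": 0.0, "mixed": 0.0},
            activity_type_missing_prob=0.0,
            seed=5,
        )
        _, sessions = generate_cohort(cfg)
        assert {s.activity_type for s in sessions} == {"aerobic"}

    def test_sessions_never_overlap(self, default_cohort):
        cfg, participants, sessions, windows, traces = default_cohort
        by_pid: dict[str, list] = {}
        for s in sessions:
            by_pid.setdefault(s.participant_id, []).append(s)
        for group in by_pid.values():
            group = sorted(group, key=lambda s: s.start)
            assert all(a.end <= b.start for a, b in zip(group, group[1:]))

    def test_seed_substreams_stable_under_cohort_growth(self):
        """Adding participants never reshuffles earlier participants."""
        small = default_config(n_participants=5, study_days=10, seed=11)
        large = default_config(n_participants=9, study_days=10, seed=11)
        _, s_small = generate_cohort(small)
        _, s_large = generate_cohort(large)
        prefix = [s for s in s_large if s.participant_id in {f"P{i:03d}" for i in range(5)}]
        assert [(s.session_id, s.start, s.duration_min) for s in s_small] == [
            (s.session_id, s.start, s.duration_min) for s in prefix
        ]


class TestSynthesizeTraces:
    def test_degenerate_occupancy_pins_all_readings_in_range(self):
        from periglyc.config import BandOccupancy

        cfg = default_config(
            n_participants=4,
            study_days=6,
            band_occupancy_by_window={
                wc: BandOccupancy(0, 0, 1.0, 0, 0)
                for wc in ("PRE", "DURING", "EARLY", "LATE", "NONEX")
            },
            cgm_missing_session_prob=0.0,
            seed=3,
        )
        _, _, _, traces = run_pipeline(cfg)
        for tr in traces:
            assert ((tr.glucose >= 70) & (tr.glucose <= 180)).all()

    def test_all_sessions_missing_removes_during_readings(self):
        cfg = default_config(
            n_participants=4, study_days=6, cgm_missing_session_prob=1.0, seed=3
        )
        _, sessions, windows, traces = run_pipeline(cfg)
        by_pid = {tr.participant_id: tr for tr in traces}
        for s in sessions:
            tr = by_pid[s.participant_id]
            lo = np.datetime64(s.start, "s")
            hi = np.datetime64(s.end, "s")
            assert not ((tr.times >= lo) & (tr.times < hi)).any()

    def test_grid_is_five_minutes_with_gaps_only_at_deletions(self, small_cohort):
        cfg, participants, sessions, windows, traces = small_cohort
        for tr in traces:
            steps = np.diff(tr.times).astype("timedelta64[s]").astype(int)
            assert (steps % 300 == 0).all() and (steps > 0).all()

    def test_markov_persistence_preserves_window_marginals(self):
        """With rho > 0, runs lengthen but per-class occupancies still hold."""
        cfg0 = default_config(n_participants=20, study_days=20,
                              cgm_missing_session_prob=0.0, seed=77)
        cfg9 = default_config(n_participants=20, study_days=20,
                              cgm_persistence=0.9,
                              cgm_missing_session_prob=0.0, seed=77)
        occ = cfg0.band_occupancy_by_window["NONEX"].as_array()

        def nonex_band_freqs(cfg):
            _, sessions, windows, traces = run_pipeline(cfg)
            counts = np.zeros(5)
            switches = total = 0
            for tr in traces:
                wins = sorted(
                    (w for w in windows if w.participant_id == tr.participant_id),
                    key=lambda w: w.interval.start,
                )
                starts, ends, codes, _ = window_bounds_arrays(wins)
                idx = np.searchsorted(starts, tr.times, side="right") - 1
                nonex = codes[idx] == 4
                band = np.digitize(tr.glucose, [54, 70, 181, 251])
                counts += np.bincount(band[nonex], minlength=5)
                switches += int((np.diff(band) != 0).sum())
                total += len(band) - 1
            return (counts / counts.sum(), counts.sum()), switches / total

        (freq0, n0), switch0 = nonex_band_freqs(cfg0)
        (freq9, n9), switch9 = nonex_band_freqs(cfg9)
        assert np.all(np.abs(freq0 - occ) <= 3 * np.sqrt(occ * (1 - occ) / n0))
        # marginals hold under persistence too, with variance inflated by
        # the autocorrelation factor (1+rho)/(1-rho)
        infl = np.sqrt((1 + 0.9) / (1 - 0.9))
        assert np.all(np.abs(freq9 - occ) <= 3 * infl * np.sqrt(occ * (1 - occ) / n9))
        assert switch9 < 0.5 * switch0


class TestDatasetIO:
    def test_round_trip_identity(self, small_cohort):
        cfg, participants, sessions, windows, traces = small_cohort
        out = Path(__import__("tempfile").mkdtemp())
        write_dataset(participants, sessions, traces, out)
        p2, s2, t2 = read_dataset(out)
        assert p2 == list(participants)
        assert s2 == list(sessions)
        assert len(t2) == len(traces)
        for a, b in zip(sorted(traces, key=lambda t: t.participant_id), t2):
            assert a.participant_id == b.participant_id
            assert (a.times == b.times).all()
            assert (a.glucose == b.glucose).all()

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = default_config(n_participants=4, study_days=6, seed=99)
        for d in ("one", "two"):
            participants, sessions, windows, traces = run_pipeline(cfg)
            write_dataset(participants, sessions, traces, tmp_path / d)
        assert _dir_hashes(tmp_path / "one") == _dir_hashes(tmp_path / "two")

    def test_empty_cohort_writes_headers_only(self, tmp_path):
        write_dataset([], [], [], tmp_path)
        for name in ("participants", "sessions", "episodes", "carbs", "cgm"):
            lines = (tmp_path / f"{name}.csv").read_text().strip().splitlines()
            assert len(lines) == 1

    def test_cgm_row_count_matches_grid_minus_deletions(self, small_cohort, tmp_path):
        cfg, participants, sessions, windows, traces = small_cohort
        paths = write_dataset(participants, sessions, traces, tmp_path)
        n_rows = len(Path(paths["cgm"]).read_text().strip().splitlines()) - 1
        grid_total = len(participants) * cfg.study_days * 288
        deleted = grid_total - sum(len(t) for t in traces)
        assert n_rows == grid_total - deleted
        assert deleted > 0  # default config deletes some sessions' CGM


def test_base_log_odds_inversion_matches_marginal():
    """solve_base_log_odds is the exact inverse of random-intercept averaging."""
    rng = np.random.default_rng(1)
    for p, sigma in [(0.2, 0.0), (0.2, 0.5), (0.05, 1.5), (0.6, 1.0)]:
        alpha = solve_base_log_odds(p, sigma)
        b = rng.normal(0, sigma, 400_000)
        emp = (1 / (1 + np.exp(-(alpha + b)))).mean()
        assert emp == pytest.approx(p, abs=4e-3)


def test_logbook_marginals_recover_configured_probabilities(default_cohort):
    """Empirical per-session prevalences match the config within 3 SE."""
    cfg, participants, sessions, windows, traces = default_cohort
    n = len(sessions)

    def check(observed_frac, p):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed_frac - p) <= 3 * se

    check(sum(1 for s in sessions if s.carbs_before) / n, cfg.carb_before_prob)
    check(sum(1 for s in sessions if s.carbs_during) / n, cfg.carb_during_prob)
    check(
        sum(1 for s in sessions if s.adjustment_data_available) / n,
        1 - cfg.adjustment_missing_prob,
    )
    tt_none = sum(1 for s in sessions if s.temp_target_offset_min is None) / n
    check(tt_none, cfg.temp_target_category_probs["none"])
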