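"""Band assignment and pooled window metrics."""

from __future__ import annotations

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from periglyc.cgm_metrics import (
    BAND_LABELS,
    BandDefinition,
    band_of,
    compute_window_metrics,
    metrics_table,
    render_console,
)
from periglyc.records import GlucoseTrace
from periglyc.windowing import Interval, LabeledWindow

D0 = datetime(2024, 4, 1)


def mk_trace(pid, start, values, step_min=5):
    times = np.array(
        [np.datetime64(start + timedelta(minutes=step_min * i), "s")
         for i in range(len(values))]
    )
    return GlucoseTrace(pid, times, np.array(values))


def mk_window(pid, start, end, wc, sid=None):
    return LabeledWindow(Interval(start, end), wc, sid, pid)


class TestBandOf:
    @pytest.mark.parametrize(
        "glucose, label",
        [
            (40, "<54"), (53, "<54"), (54, "54-69"), (69, "54-69"),
            (70, "70-180"), (180, "70-180"), (181, "181-250"),
            (250, "181-250"), (251, ">250"), (400, ">250"),
        ],
    )
    def test_boundaries(self, glucose, label):
        assert band_of(glucose) == label

    @pytest.mark.parametrize("glucose", [39, 401, -5])
    def test_out_of_range_rejected(self, glucose):
        with pytest.raises(ValueError, match="sensor range"):
            band_of(glucose)

    def test_non_contiguous_band_definition_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            BandDefinition((("a", 40, 60), ("b", 62, 400)))


class TestComputeWindowMetrics:
    def test_constant_in_range_trace_gives_full_tir(self):
        windows = [mk_window("P0", D0, D0 + timedelta(hours=4), "NONEX")]
        traces = [mk_trace("P0", D0, [100] * 48)]
        metrics, excluded = compute_window_metrics(traces, windows)
        assert excluded == 0
        assert metrics["NONEX"].tir_pct == 100.0
        assert metrics["NONEX"].n_readings == 48

    def test_hand_tally_across_pre_during_boundary(self):
        """12 readings straddling PRE|DURING agree with a manual count."""
        t_split = D0 + timedelta(minutes=30)
        windows = [
            mk_window("P0", D0, t_split, "PRE", "s1"),
            mk_window("P0", t_split, D0 + timedelta(hours=2), "DURING", "s1"),
        ]
        # readings at 0,5,...,55 min; boundary reading (t=30) is DURING
        values = [65, 100, 100, 200, 52, 100, 68, 68, 300, 100, 100, 180]
        traces = [mk_trace("P0", D0, values)]
        metrics, _ = compute_window_metrics(traces, windows)
        pre, during = metrics["PRE"], metrics["DURING"]
        assert pre.n_readings == 6 and during.n_readings == 6
        assert pre.pct_by_band["54-69"] == pytest.approx(100 * 1 / 6)  # the 65
        assert pre.pct_by_band["<54"] == pytest.approx(100 * 1 / 6)  # the 52
        assert pre.pct_by_band["181-250"] == pytest.approx(100 * 1 / 6)  # the 200
        assert during.pct_by_band["54-69"] == pytest.approx(100 * 2 / 6)
        assert during.pct_by_band[">250"] == pytest.approx(100 * 1 / 6)
        assert during.tbr_total_pct == pytest.approx(100 * 2 / 6)

    def test_empty_class_reported_as_nan_not_zero(self):
        windows = [mk_window("P0", D0, D0 + timedelta(hours=1), "NONEX")]
        traces = [mk_trace("P0", D0, [100] * 12)]
        metrics, _ = compute_window_metrics(traces, windows)
        assert metrics["PRE"].n_readings == 0
        assert math.isnan(metrics["PRE"].tir_pct)
        assert all(math.isnan(v) for v in metrics["PRE"].pct_by_band.values())

    def test_readings_outside_span_are_excluded_and_counted(self):
        windows = [mk_window("P0", D0, D0 + timedelta(minutes=30), "NONEX")]
        traces = [mk_trace("P0", D0 - timedelta(minutes=10), [100] * 12)]
        metrics, excluded = compute_window_metrics(traces, windows)
        assert excluded == 6  # 2 before the span + 4 at or past its end
        assert metrics["NONEX"].n_readings == 6

    def test_band_percentages_sum_to_100(self, small_cohort):
        cfg, participants, sessions, windows, traces = small_cohort
        metrics, excluded = compute_window_metrics(traces, windows)
        total = sum(m.n_readings for m in metrics.values()) + excluded
        assert total == sum(len(t) for t in traces)
        for m in metrics.values():
            if m.n_readings:
                assert sum(m.pct_by_band.values()) == pytest.approx(100.0, abs=1e-6)

    def test_pooled_equals_reading_weighted_mean_of_participants(self, small_cohort):
        """Pooling identity: cohort % = count-weighted mean of per-trace %."""
        cfg, participants, sessions, windows, traces = small_cohort
        pooled, _ = compute_window_metrics(traces, windows)
        for wc in ("DURING", "NONEX"):
            num = den = 0.0
            for tr in traces:
                m_i, _ = compute_window_metrics(
                    [tr], [w for w in windows if w.participant_id == tr.participant_id]
                )
                if m_i[wc].n_readings:
                    num += m_i[wc].tbr_total_pct * m_i[wc].n_readings
                    den += m_i[wc].n_readings
            assert pooled[wc].tbr_total_pct == pytest.approx(num / den, abs=1e-9)

    def test_tbr_band_sum_equals_direct_below70_count(self, small_cohort):
        """Threshold consistency: two routes to TBR agree exactly."""
        from periglyc.windowing import window_bounds_arrays

        cfg, participants, sessions, windows, traces = small_cohort
        metrics, _ = compute_window_metrics(traces, windows)
        counts = {wc: [0, 0] for wc in metrics}  # below 70, total
        for tr in traces:
            wins = sorted(
                (w for w in windows if w.participant_id == tr.participant_id),
                key=lambda w: w.interval.start,
            )
            starts, _, codes, _ = window_bounds_arrays(wins)
            idx = np.searchsorted(starts, tr.times, side="right") - 1
            for wc_i, wc in enumerate(("PRE", "DURING", "EARLY", "LATE", "NONEX")):
                sel = codes[idx] == wc_i
                counts[wc][0] += int((tr.glucose[sel] < 70).sum())
                counts[wc][1] += int(sel.sum())
        for wc, (below, total) in counts.items():
            if total:
                assert metrics[wc].tbr_total_pct == pytest.approx(
                    100 * below / total, abs=1e-9
                )

    def test_participant_mean_pooling_differs_but_stays_close(self, small_cohort):
        cfg, participants, sessions, windows, traces = small_cohort
        pooled, _ = compute_window_metrics(traces, windows, pooling="readings")
        bymean, _ = compute_window_metrics(traces, windows, pooling="participant_mean")
        assert bymean["NONEX"].tir_pct == pytest.approx(pooled["NONEX"].tir_pct, abs=5)

    def test_unknown_pooling_rejected(self, small_cohort):
        cfg, participants, sessions, windows, traces = small_cohort
        with pytest.raises(ValueError, match="pooling"):
            compute_window_metrics(traces, windows, pooling="bogus")


class TestMetricsTable:
    def test_empty_metrics_gives_headers_only(self):
        table = metrics_table({})
        assert len(table) == 0
        assert list(table.columns)[:3] == ["window_class", "n_readings", "hours"]

    def test_default_cohort_has_five_rows(self, small_cohort):
        cfg, participants, sessions, windows, traces = small_cohort
        metrics, _ = compute_window_metrics(traces, windows)
        table = metrics_table(metrics)
        assert list(table["window_class"]) == ["PRE", "DURING", "EARLY", "LATE", "NONEX"]

    def test_console_view_rounds_to_integers(self, small_cohort):
        cfg, participants, sessions, windows, traces = small_cohort
        metrics, _ = compute_window_metrics(traces, windows)
        table = metrics_table(metrics)
        console = render_console(table)
        for token in console.splitlines()[1].split()[3:]:
            assert float(token) == round(float(token))
        # CSV table keeps full precision
        assert any(v != round(v) for v in table["tir"])
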