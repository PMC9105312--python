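"""Smoothing, event extraction, margin matching, rates and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focalwear.scoring import (
    EventSet,
    far24,
    farn,
    match,
    mean_fold_sensitivity,
    night_hours_recorded,
    permutation_null,
    pooled_sensitivity,
    score_events,
    smooth,
    smooth_series,
    to_events,
)
from focalwear.signal_model import MultimodalRecording, Segment, TimeSeriesChannel


def _labels(spec, n=400):
    """Build a label array from [(start_idx, length), ...] runs of ones."""
    x = np.zeros(n, dtype=int)
    for start, length in spec:
        x[start : start + length] = 1
    return x


def _recording(hours=24.0, start=0.0, utc_offset=0.0, gaps=()):
    segs = []
    bounds, cursor = [], 0.0
    total = hours * 3600
    for off, dur in sorted(gaps):
        bounds.append((cursor, off))
        cursor = off + dur
    bounds.append((cursor, total))
    for a, b in bounds:
        if b <= a:
            continue
        seg = Segment(start_time=start + a)
        seg.channels["EDA"] = TimeSeriesChannel(
            "EDA", start + a, 4.0, np.zeros(int((b - a) * 4))
        )
        segs.append(seg)
    return MultimodalRecording("S", segments=segs, utc_offset_hours=utc_offset)


class TestSmooth:
    def test_fill_30s_gap(self):
        # two 10-s runs separated by a 20-s gap -> one 40-s run
        x = _labels([(50, 5), (65, 5)], n=100)
        out = smooth(x)
        assert out[50:70].all()
        assert out.sum() == 20

    def test_do_not_fill_32s_gap(self):
        x = _labels([(50, 5), (71, 5)], n=100)
        out = smooth(x)
        assert not out[55:71].any()

    def test_orphan_removed(self):
        assert smooth(_labels([(50, 1)], n=100)).sum() == 0
        assert smooth(_labels([(50, 2)], n=100)).sum() == 0
        assert smooth(_labels([(50, 3)], n=100)).sum() == 3

    def test_orphans_merged_by_fill_survive(self):
        # two 2-interval runs 10 s apart merge into one 18-s run, kept
        x = _labels([(50, 2), (57, 2)], n=100)
        assert smooth(x).sum() == 9

    @given(st.lists(st.integers(0, 1), min_size=0, max_size=120))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, bits):
        x = np.array(bits, dtype=int)
        once = smooth(x)
        np.testing.assert_array_equal(once, smooth(once))

    def test_never_bridges_recording_gaps(self):
        times = np.concatenate([np.arange(0, 100, 2.0), np.arange(500, 600, 2.0)])
        labels = np.zeros(times.shape[0], dtype=int)
        labels[48:50] = 1  # last 2 intervals of segment 1
        labels[50:52] = 1  # first 2 intervals of segment 2
        out = smooth_series(labels, times)
        assert out.sum() == 0  # each side is an orphan within its segment


class TestToEvents:
    def test_below_minimum_dropped(self):
        ev = to_events(_labels([(10, 2)]), np.arange(400) * 2.0)
        assert len(ev) == 0

    def test_exact_minimum_kept(self):
        ev = to_events(_labels([(10, 3)]), np.arange(400) * 2.0)
        assert list(ev) == [(20.0, 26.0)]

    def test_long_run_truncated_once(self):
        ev = to_events(_labels([(10, 350)], n=400), np.arange(400) * 2.0)
        assert len(ev) == 1
        (s, e), = list(ev)
        assert e - s == 600.0


class TestMatch:
    def test_direct_overlap_tp(self):
        m = match(EventSet([(100, 160)]), EventSet([(150, 200)]))
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_margin_tp_90s_after_offset(self):
        m = match(EventSet([(100, 160)]), EventSet([(250, 270)]))
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_isolated_prediction_fp(self):
        m = match(EventSet([(100, 160)]), EventSet([(1000, 1020)]))
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_multiple_overlaps_absorbed(self):
        m = match(EventSet([(100, 160)]), EventSet([(90, 110), (150, 170), (250, 260)]))
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    @given(
        st.lists(st.tuples(st.integers(0, 500), st.integers(3, 20)), max_size=5),
        st.lists(st.tuples(st.integers(0, 500), st.integers(3, 20)), max_size=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_counting_invariants_and_margin_monotonicity(self, truth_spec, pred_spec):
        def mk(spec):
            events, cursor = [], 0
            for gap, length in spec:
                start = cursor + gap
                events.append((float(start), float(start + length)))
                cursor = start + length
            return EventSet(events)

        truth, pred = mk(truth_spec), mk(pred_spec)
        prev_tp = -1
        for margin in (0, 30, 120, 500):
            m = match(truth, pred, margin_s=margin)
            assert m.tp + m.fn == len(truth)
            assert m.tp + m.fp <= len(truth) + len(pred)
            assert m.fp == len(pred) - sum(
                1
                for ps, pe in pred
                if any(ps <= te + margin and pe >= ts - margin for ts, te in truth)
            )
            assert m.tp >= prev_tp  # monotone in margin
            prev_tp = m.tp


class TestRates:
    @pytest.mark.parametrize(
        "fp,hours,expected",
        [(3, 84.4, 0.85), (37, 50.2, 17.69), (28, 84.4, 7.96), (1, 50.2, 0.48), (0, 84.4, 0.0)],
    )
    def test_far24_printed_values(self, fp, hours, expected):
        assert round(far24(fp, hours), 2) == expected

    def test_far24_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            far24(1, 0.0)

    def test_farn_formula(self):
        # recording spans 2 full days from midnight: 16 h of night data
        rec = _recording(hours=48.0)
        rate, fp_night, nightly = farn([(2 * 3600.0, None), (24 * 3600.0 + 3600, None)], rec)
        assert nightly == pytest.approx(16.0)
        assert fp_night == 2  # both FPs start between 23:00 and 07:00
        assert rate == pytest.approx(1.0)

    def test_farn_night_attribution_by_start(self):
        rec = _recording(hours=24.0)
        assert farn([(12 * 3600.0, None)], rec)[1] == 0  # noon start: not night

    def test_night_hours_with_dropout_schedule(self):
        # 24-h day with a 2-h gap covering 01:00-03:00 -> 6 h night recorded
        rec = _recording(hours=24.0, gaps=[(1 * 3600.0, 2 * 3600.0)])
        assert night_hours_recorded(rec) == pytest.approx(6.0)

    def test_farn_undefined_without_night_coverage(self):
        rec = _recording(hours=2.0, start=8 * 3600.0)  # 08:00-10:00 only
        rate, _, nightly = farn([], rec)
        assert nightly == 0
        assert np.isnan(rate)


class TestAggregation:
    def test_pooled_vs_mean_fold_counts(self):
        # fold detections 3/6, 3/3, 2/3
        tps, totals = [3, 3, 2], [6, 3, 3]
        assert round(100 * pooled_sensitivity(tps, totals)) == 67
        assert round(100 * mean_fold_sensitivity(tps, totals)) == 72

    def test_score_events_report(self):
        rec = _recording(hours=24.0)
        truth = EventSet([(10_000.0, 10_060.0), (40_000.0, 40_030.0)])
        pred = EventSet([(10_010.0, 10_050.0), (70_000.0, 70_020.0)])
        r = score_events(truth, pred, rec)
        assert (r.tp, r.fp, r.fn) == (1, 1, 1)
        assert r.sensitivity == 0.5
        assert r.ppv == 0.5
        assert r.far24 == pytest.approx(1.0)
        assert r.recording_hours == pytest.approx(24.0)


class TestPermutationNull:
    def test_no_predictions_gives_zero_null(self):
        rec = _recording(hours=10.0)
        counts = permutation_null(EventSet([]), EventSet([(5000.0, 5050.0)]), rec, n_reps=20)
        assert counts.sum() == 0

    def test_dense_predictions_saturate_null(self):
        rec = _recording(hours=1.0)
        # gaps between predictions (150 s) are smaller than the extended
        # truth width (50 s + 2 x 120 s margin): every placement must hit
        pred = EventSet([(i * 250.0, i * 250.0 + 100.0) for i in range(15)])
        counts = permutation_null(pred, EventSet([(100.0, 150.0)]), rec, n_reps=20)
        assert (counts == 1).all()
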