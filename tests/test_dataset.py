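"""Feature-grid assembly, labels, peri-ictal splits, normalization and the
cohort selection filters."""

import numpy as np
import pandas as pd
import pytest

from focalwear.dataset import (
    FEATURE_NAMES,
    SelectionCriteria,
    build_feature_grid,
    eda_quality_flags,
    extract_periictal,
    filter_recordings,
    filter_seizures,
    make_labels,
    zscore_apply,
    zscore_fit,
)
from focalwear.signal_model import (
    MultimodalRecording,
    Segment,
    SeizureAnnotation,
    TimeSeriesChannel,
)
from focalwear.synthetic import SyntheticProfile, generate_participant


def _ann(sid, onset, offset):
    return SeizureAnnotation(sid, onset, offset)


@pytest.fixture(scope="module")
def hour_grid(quiet_profile_module):
    rec, _ = generate_participant(quiet_profile_module, total_hours=1.0, n_seizures=0, seed=1,
                                  start_time=0.0)
    return build_feature_grid(rec)


@pytest.fixture(scope="module")
def quiet_profile_module():
    return SyntheticProfile(
        "QGRID", acc_noise_g=0.001, eda_noise_us=0.001, bvp_noise=0.1,
        scr_rate_awake_per_min=0.0, scr_rate_asleep_per_min=0.0,
        baseline_activity_level=0.0,
    )


class TestFeatureGrid:
    def test_one_hour_is_1800_points(self, hour_grid):
        assert hour_grid.n_points == 1800

    def test_canonical_column_order(self, hour_grid):
        assert tuple(hour_grid.features.columns) == tuple(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 11

    def test_gap_has_no_grid_points(self, quiet_profile_module):
        rec, _ = generate_participant(
            quiet_profile_module, total_hours=1.0, n_seizures=0, seed=2,
            start_time=0.0, dropouts=[(1200.0, 600.0)],
        )
        grid = build_feature_grid(rec)
        inside_gap = (grid.grid_times >= 1200.0) & (grid.grid_times < 1800.0)
        assert not inside_gap.any()
        assert grid.n_points == 1800 - 300


class TestLabels:
    def test_interval_overlap_count(self, hour_grid):
        labels = make_labels([_ann("s", 100.0, 160.0)], hour_grid)
        # half-open [t, t+2) grid intervals against the closed interval
        # [100, 160]: t = 100..160 -> 31 intervals
        assert labels.labels.sum() == 31
        assert labels.labels[50:81].all()

    def test_no_annotations_all_zero(self, hour_grid):
        assert make_labels([], hour_grid).labels.sum() == 0

    def test_seizure_within_one_interval(self, hour_grid):
        labels = make_labels([_ann("s", 200.5, 201.5)], hour_grid)
        assert labels.labels.sum() == 1
        assert labels.labels[100] == 1

    def test_order_invariance_and_idempotence(self, hour_grid):
        anns = [_ann("a", 100, 160), _ann("b", 500, 530)]
        l1 = make_labels(anns, hour_grid)
        l2 = make_labels(anns[::-1], hour_grid)
        np.testing.assert_array_equal(l1.labels, l2.labels)


class TestPeriIctal:
    def test_single_seizure_row_count(self, hour_grid):
        split = extract_periictal(hour_grid, [_ann("s", 1500.0, 1560.0)], guard_s=0.0)
        # 600 + 60 + 600 = 1260 s -> 630 grid rows
        assert split.train_idx.size == 630

    def test_overlapping_pads_union(self, hour_grid):
        split = extract_periictal(
            hour_grid, [_ann("a", 1500.0, 1560.0), _ann("b", 1700.0, 1760.0)], guard_s=0.0
        )
        # spans [900,2160] and [1100,2360] merge into [900,2360] -> 1460 s
        assert len(split.train_spans) == 1
        assert split.train_idx.size == 730

    def test_pad_zero_is_ictal_rows(self, hour_grid):
        split = extract_periictal(hour_grid, [_ann("s", 100.0, 160.0)], pad_s=0.0, guard_s=0.0)
        labels = make_labels([_ann("s", 100.0, 160.0)], hour_grid)
        label_rows = np.flatnonzero(labels.labels)
        # the ictal rows, up to the measure-zero boundary interval that only
        # touches the offset instant
        assert set(split.train_idx) <= set(label_rows)
        assert split.train_idx.size >= label_rows.size - 1

    def test_disjoint_and_guard(self, hour_grid):
        split = extract_periictal(hour_grid, [_ann("s", 1500.0, 1560.0)])
        assert np.intersect1d(split.train_idx, split.test_idx).size == 0
        t = hour_grid.grid_times
        # guard band: no test row within 600 s of the training span
        assert not ((t[split.test_idx] > 300.0) & (t[split.test_idx] < 2760.0)).any()


class TestZScore:
    def _frame(self, rng, n=200):
        return pd.DataFrame(
            {name: rng.normal(loc=i, scale=1 + i, size=n) for i, name in enumerate(FEATURE_NAMES)}
        )

    def test_fit_apply_standardizes(self, rng):
        X = self._frame(rng)
        params = zscore_fit(X)
        Z = zscore_apply(params, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_column_rejected_by_name(self, rng):
        X = self._frame(rng)
        X["f_eda_dmax"] = 3.14
        with pytest.raises(ValueError, match="f_eda_dmax"):
            zscore_fit(X)

    def test_no_dependence_on_test_rows(self, rng):
        """Stored parameters are independent of the test set: permuting test
        rows permutes the output rows exactly (no re-fitting leak)."""
        X_train, X_test = self._frame(rng), self._frame(rng, n=50)
        params = zscore_fit(X_train)
        Z = zscore_apply(params, X_test)
        perm = rng.permutation(50)
        Z_perm = zscore_apply(params, X_test.iloc[perm])
        np.testing.assert_array_equal(Z[perm], Z_perm)

    def test_masked_entries_imputed_to_training_mean(self, rng):
        X = self._frame(rng)
        params = zscore_fit(X)
        valid = pd.DataFrame(True, index=X.index, columns=X.columns)
        valid.iloc[0, 0] = False
        Z = zscore_apply(params, X, valid)
        assert Z[0, 0] == 0.0


class TestSelectionFilters:
    def test_seizure_duration_bounds(self):
        anns = [_ann("a", 0, 8), _ann("b", 100, 130), _ann("c", 1000, 1540), _ann("d", 5000, 5660)]
        kept, log = filter_seizures(anns)
        assert [a.seizure_id for a in kept] == ["b", "c"]
        assert {e["seizure_id"]: e["rule"] for e in log} == {
            "a": "duration_below_min",
            "d": "duration_above_max",
        }

    def test_recording_hours_bound(self):
        def rec(pid, hours):
            seg = Segment(0.0)
            seg.channels["EDA"] = TimeSeriesChannel("EDA", 0.0, 4.0, np.zeros(int(hours * 3600 * 4)))
            return MultimodalRecording(pid, segments=[seg])

        kept, log = filter_recordings([rec("short", 20), rec("long", 25)])
        assert [r.participant_id for r in kept] == ["long"]
        assert log[0]["rule"] == "recording_below_min_hours"

    def test_empty_inputs(self):
        assert filter_seizures([]) == ([], [])
        assert filter_recordings([]) == ([], [])


class TestEDAQuality:
    def _rec(self, eda):
        seg = Segment(0.0)
        seg.channels["EDA"] = TimeSeriesChannel("EDA", 0.0, 4.0, np.asarray(eda, float))
        return MultimodalRecording("Q", segments=[seg])

    def test_flat_zero(self):
        flags = eda_quality_flags(self._rec(np.zeros(4 * 2000)), _ann("s", 800, 860))
        assert flags["flat_zero"] and not flags["unstable"]

    def test_unstable_square_wave(self):
        x = np.tile([10.0, -10.0], 4 * 1000)
        flags = eda_quality_flags(self._rec(x), _ann("s", 800, 860))
        assert flags["unstable"]

    def test_smooth_responder_clean(self, quiet_profile):
        rec, ann = generate_participant(quiet_profile, total_hours=1.0, n_seizures=1, seed=4)
        flags = eda_quality_flags(rec, ann[0])
        assert flags == {"flat_zero": False, "unstable": False}
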