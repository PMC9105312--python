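"""Event-based detection scoring and the cross-validation harnesses.

Per-interval predictions on the 2-s grid are first smoothed (gaps of at most
30 s between seizure labels are filled, then orphan runs shorter than the
6-s event minimum are removed) and collapsed into *events*: maximal runs of
seizure labels lasting between 6 s and 10 min.  Events are matched against
expert-labeled ground truth with a 2-min margin on both sides of each true
seizure; any overlapping prediction counts the seizure as detected (one true
positive, however many predictions overlap), unmatched truth events are
false negatives, and predictions overlapping no extended truth event are
false positives.  True negatives are never counted.

Rates: FAR24 = FP x 24 / recorded hours; FARn = FP starting during the
standard night (23:00-07:00 local) x 8 / nightly hours actually recorded.

Two evaluation harnesses mirror the two study designs: a per-participant
leave-one-seizure-out run (train on the peri-ictal surround of all other
seizures, test on everything not used for training) and a
leave-one-participant-out run whose optimized model is finally applied to
the complete recordings of held-out test participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    ParticipantData,
    extract_periictal,
    zscore_apply,
    zscore_fit,
)
from .detector import GTBMParams, ModelBundle, grid_search, importance, train
from .grid import GRID_STEP_S
from .signal_model import MultimodalRecording, recording_hours

__all__ = [
    "EventSet",
    "ScoreReport",
    "MatchResult",
    "smooth",
    "smooth_series",
    "to_events",
    "match",
    "far24",
    "farn",
    "night_hours_recorded",
    "pooled_sensitivity",
    "mean_fold_sensitivity",
    "score_events",
    "run_intra_subject",
    "run_inter_subject",
    "permutation_null",
    "IntraSubjectResult",
    "InterSubjectResult",
]

MAX_GAP_S = 30.0
MIN_EVENT_S = 6.0
MAX_EVENT_S = 600.0
MATCH_MARGIN_S = 120.0
NIGHT_START_H = 23
NIGHT_END_H = 7
HOURS_PER_NIGHT = 8.0


@dataclass
class EventSet:
    """Sorted, non-overlapping [start, end] intervals in epoch seconds."""

    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted((float(a), float(b)) for a, b in self.events)
        for (a, b), (c, _) in zip(self.events, self.events[1:]):
            if c < b:
                raise ValueError("events overlap")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_truth: list[tuple[float, float]]
    missed_truth: list[tuple[float, float]]
    fp_events: list[tuple[float, float]]


@dataclass
class ScoreReport:
    """Event-level counts and rates for one evaluation unit (fold or
    participant).  ``ppv`` is defined as 0 when no positive was predicted."""

    tp: int
    fp: int
    fn: int
    sensitivity: float
    far24: float
    farn: float
    ppv: float
    recording_hours: float
    nightly_hours_recorded: float
    fp_night: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _run_bounds(x: np.ndarray) -> list[tuple[int, int, int]]:
    """(value, start, stop) runs of a 1-D integer array; stop exclusive."""
    if x.shape[0] == 0:
        return []
    change = np.flatnonzero(np.diff(x) != 0) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [x.shape[0]]))
    return [(int(x[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def smooth(pred_labels: np.ndarray, step_s: float = GRID_STEP_S) -> np.ndarray:
    """Fill gaps of at most 30 s between seizure labels, then remove orphan
    runs shorter than the 6-s event minimum.  Idempotent.

    Operates on one contiguous label series; use :func:`smooth_series` for a
    grid spanning recording gaps.
    """
    x = np.asarray(pred_labels, dtype=int).copy()
    max_gap = int(np.floor(MAX_GAP_S / step_s + 1e-9))
    min_run = int(np.ceil(MIN_EVENT_S / step_s - 1e-9))
    runs = _run_bounds(x)
    for i, (v, a, b) in enumerate(runs):
        if v == 0 and 0 < i < len(runs) - 1 and (b - a) <= max_gap:
            x[a:b] = 1
    for v, a, b in _run_bounds(x):
        if v == 1 and (b - a) < min_run:
            x[a:b] = 0
    return x


def _segment_slices(grid_times: np.ndarray, step_s: float) -> list[slice]:
    if grid_times.shape[0] == 0:
        return []
    breaks = np.flatnonzero(np.diff(grid_times) > step_s + 1e-9) + 1
    edges = np.concatenate(([0], breaks, [grid_times.shape[0]]))
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def smooth_series(
    pred_labels: np.ndarray, grid_times: np.ndarray, step_s: float = GRID_STEP_S
) -> np.ndarray:
    """Apply :func:`smooth` within each contiguous stretch of the grid
    (smoothing never bridges recording gaps)."""
    out = np.asarray(pred_labels, dtype=int).copy()
    for sl in _segment_slices(np.asarray(grid_times, dtype=float), step_s):
        out[sl] = smooth(out[sl], step_s)
    return out


def to_events(
    labels: np.ndarray, grid_times: np.ndarray, step_s: float = GRID_STEP_S
) -> EventSet:
    """Maximal seizure-label runs of 6 s to 10 min as [start, end] events.

    Runs longer than 10 min are truncated to their first 600 s and counted
    once.  Runs never cross recording gaps.
    """
    labels = np.asarray(labels, dtype=int)
    grid_times = np.asarray(grid_times, dtype=float)
    events: list[tuple[float, float]] = []
    for sl in _segment_slices(grid_times, step_s):
        for v, a, b in _run_bounds(labels[sl]):
            if v != 1:
                continue
            start = grid_times[sl.start + a]
            end = grid_times[sl.start + b - 1] + step_s
            dur = end - start
            if dur < MIN_EVENT_S:
                continue
            if dur > MAX_EVENT_S:
                end = start + MAX_EVENT_S
            events.append((start, end))
    return EventSet(events)


def match(
    truth: EventSet, pred: EventSet, margin_s: float = MATCH_MARGIN_S
) -> MatchResult:
    """Margin-based event matching.

    Each truth event is extended by ``margin_s`` on both sides; a truth event
    overlapped by at least one prediction is one TP (extra overlapping
    predictions are absorbed, not FPs).  Predictions overlapping no extended
    truth event are FPs.
    """
    matched, missed = [], []
    pred_used = np.zeros(len(pred), dtype=bool)
    pred_list = list(pred)
    for ts, te in truth:
        lo, hi = ts - margin_s, te + margin_s
        hits = [i for i, (ps, pe) in enumerate(pred_list) if ps <= hi and pe >= lo]
        if hits:
            matched.append((ts, te))
            pred_used[hits] = True
        else:
            missed.append((ts, te))
    fp_events = [ev for i, ev in enumerate(pred_list) if not pred_used[i]]
    return MatchResult(
        tp=len(matched),
        fp=len(fp_events),
        fn=len(missed),
        matched_truth=matched,
        missed_truth=missed,
        fp_events=fp_events,
    )


def far24(fp: int, recording_hours: float) -> float:
    """False alarms per 24 recorded hours: fp x 24 / hours."""
    if recording_hours <= 0:
        raise ValueError("recording_hours must be positive")
    return fp * 24.0 / recording_hours


def _is_night(t_epoch: float, utc_offset_hours: float) -> bool:
    tod = (t_epoch + utc_offset_hours * 3600.0) % 86400.0
    return tod >= NIGHT_START_H * 3600.0 or tod < NIGHT_END_H * 3600.0


def night_hours_recorded(recording: MultimodalRecording) -> float:
    """Recorded hours overlapping local 23:00-07:00 (data loss excluded)."""
    total = 0.0
    off = recording.utc_offset_hours * 3600.0
    for seg in recording.segments:
        s, e = seg.start_time + off, seg.end_time + off
        day0, day1 = int(np.floor(s / 86400.0)), int(np.floor(e / 86400.0))
        for day in range(day0 - 1, day1 + 1):
            base = day * 86400.0
            for a, b in (
                (base + NIGHT_START_H * 3600.0, base + 86400.0),
                (base, base + NIGHT_END_H * 3600.0),
            ):
                total += max(0.0, min(e, b) - max(s, a))
    return total / 3600.0


def farn(
    fp_events: list[tuple[float, float]], recording: MultimodalRecording
) -> tuple[float, int, float]:
    """False alarms per standard 8-h night, by event start time (local).

    Returns ``(rate, fp_night, nightly_hours)``; the rate is NaN when no
    nightly data was recorded.
    """
    nightly = night_hours_recorded(recording)
    fp_night = sum(1 for s, _ in fp_events if _is_night(s, recording.utc_offset_hours))
    if nightly <= 0:
        return float("nan"), fp_night, nightly
    return fp_night * HOURS_PER_NIGHT / nightly, fp_night, nightly


def pooled_sensitivity(tp_counts, totals) -> float:
    """Total TP over total seizures (not a mean of fold ratios)."""
    return float(np.sum(tp_counts)) / float(np.sum(totals))


def mean_fold_sensitivity(tp_counts, totals) -> float:
    """Mean of per-fold sensitivities."""
    return float(np.mean([t / n for t, n in zip(tp_counts, totals)]))


def score_events(
    truth: EventSet,
    pred: EventSet,
    recording: MultimodalRecording,
    margin_s: float = MATCH_MARGIN_S,
) -> ScoreReport:
    """Full event-level report for one evaluation unit."""
    m = match(truth, pred, margin_s)
    hours = recording_hours(recording)
    rate_n, fp_night, nightly = farn(m.fp_events, recording)
    denom = m.tp + m.fn
    sens = m.tp / denom if denom else float("nan")
    ppv = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 0.0
    return ScoreReport(
        tp=m.tp,
        fp=m.fp,
        fn=m.fn,
        sensitivity=sens,
        far24=far24(m.fp, hours),
        farn=rate_n,
        ppv=ppv,
        recording_hours=hours,
        nightly_hours_recorded=nightly,
        fp_night=fp_night,
    )


# ---------------------------------------------------------------------------
# Cross-validation harnesses


@dataclass
class _Fold:
    """Cached per-fold arrays so the grid search trains, never re-extracts."""

    train_idx: np.ndarray
    X_train: np.ndarray
    y_train: np.ndarray
    norm: object
    test_idx: np.ndarray
    X_test: np.ndarray
    test_none_valid: np.ndarray
    truth: EventSet
    seed: int


@dataclass
class IntraSubjectResult:
    participant_id: str
    best_params: GTBMParams
    score_table: pd.DataFrame
    fold_reports: list[ScoreReport]
    fold_seizure_ids: list[str]
    fold_index_sets: list[tuple[np.ndarray, np.ndarray]]
    fold_pred_events: list[EventSet]
    importances: pd.Series
    aggregate: dict


@dataclass
class InterSubjectResult:
    best_params: GTBMParams
    score_table: pd.DataFrame
    lopo_reports: dict[str, ScoreReport]
    test_reports: dict[str, ScoreReport]
    final_bundle: ModelBundle
    importances: pd.Series
    aggregate: dict


def _make_fold(
    pdata: ParticipantData,
    train_ann,
    truth: EventSet,
    pad_s: float,
    guard_s: float,
    seed: int,
) -> _Fold:
    split = extract_periictal(pdata.grid, train_ann, pad_s=pad_s, guard_s=guard_s)
    assert np.intersect1d(split.train_idx, split.test_idx).size == 0, (
        "train/test rows overlap"
    )
    feats, valid = pdata.grid.features, pdata.grid.valid
    Xdf_tr = feats.iloc[split.train_idx]
    v_tr = valid.iloc[split.train_idx]
    norm = zscore_fit(Xdf_tr, v_tr)
    X_tr = zscore_apply(norm, Xdf_tr, v_tr)
    y_tr = pdata.labels.labels[split.train_idx]
    Xdf_te = feats.iloc[split.test_idx]
    v_te = valid.iloc[split.test_idx]
    X_te = zscore_apply(norm, Xdf_te, v_te)
    none_valid = ~v_te.to_numpy(dtype=bool).any(axis=1)
    return _Fold(
        train_idx=split.train_idx,
        X_train=X_tr,
        y_train=y_tr,
        norm=norm,
        test_idx=split.test_idx,
        X_test=X_te,
        test_none_valid=none_valid,
        truth=truth,
        seed=seed,
    )


def _fold_events(pdata: ParticipantData, fold: _Fold, bundle: ModelBundle) -> EventSet:
    pred = bundle.ensemble.predict(fold.X_test).astype(int)
    pred[fold.test_none_valid] = 0
    full = np.zeros(pdata.grid.n_points, dtype=int)
    full[fold.test_idx] = pred
    smoothed = smooth_series(full, pdata.grid.grid_times)
    return to_events(smoothed, pdata.grid.grid_times)


def _eval_fold(pdata: ParticipantData, fold: _Fold, params: GTBMParams) -> tuple:
    bundle = train(fold.X_train, fold.y_train, params, fold.norm, seed=fold.seed)
    events = _fold_events(pdata, fold, bundle)
    m = match(fold.truth, events)
    sens = m.tp / len(fold.truth) if len(fold.truth) else float("nan")
    return sens, m.fp, bundle, events


def run_intra_subject(
    pdata: ParticipantData,
    param_grid: list[GTBMParams],
    min_seizures: int = 3,
    pad_s: float = 600.0,
    guard_s: float = 600.0,
    margin_s: float = MATCH_MARGIN_S,
    seed: int = 0,
) -> IntraSubjectResult:
    """Parameter-optimized leave-one-seizure-out evaluation of one
    participant.

    Each fold trains on the peri-ictal surround of all but one seizure
    (z-score fitted on those rows) and is tested on the complete remaining
    recording — including the left-out seizure, excluding every training row
    and a guard band around it.  One flat grid search optimizes over the
    mean fold scores; the winning combination's per-fold reports are
    returned, with both pooled and mean-of-folds aggregates.
    """
    ann = pdata.annotations
    if len(ann) < min_seizures:
        raise ValueError(
            f"participant {pdata.participant_id}: needs at least {min_seizures} "
            f"retained seizures, has {len(ann)}"
        )
    folds = []
    for k, left_out in enumerate(ann):
        train_ann = [a for i, a in enumerate(ann) if i != k]
        truth = EventSet([(left_out.onset, left_out.offset)])
        folds.append(
            _make_fold(pdata, train_ann, truth, pad_s, guard_s, seed * 1000 + k)
        )

    def eval_fn(params: GTBMParams, fold: _Fold) -> tuple[float, float]:
        sens, fp, _, _ = _eval_fold(pdata, fold, params)
        return sens, fp

    best, table = grid_search(folds, param_grid, eval_fn)
    reports, bundles, pred_events = [], [], []
    for fold in folds:
        _, _, bundle, events = _eval_fold(pdata, fold, best)
        reports.append(score_events(fold.truth, events, pdata.recording, margin_s))
        bundles.append(bundle)
        pred_events.append(events)
    tps = [r.tp for r in reports]
    aggregate = {
        "pooled_sensitivity": pooled_sensitivity(tps, [1] * len(reports)),
        "mean_sensitivity": mean_fold_sensitivity(tps, [1] * len(reports)),
        "mean_fp": float(np.mean([r.fp for r in reports])),
        "mean_far24": float(np.mean([r.far24 for r in reports])),
        "pooled_far24": far24(int(np.sum([r.fp for r in reports])),
                              recording_hours(pdata.recording) * len(reports)),
        "mean_farn": float(np.mean([r.farn for r in reports])),
        "mean_ppv": float(np.mean([r.ppv for r in reports])),
    }
    return IntraSubjectResult(
        participant_id=pdata.participant_id,
        best_params=best,
        score_table=table,
        fold_reports=reports,
        fold_seizure_ids=[a.seizure_id for a in ann],
        fold_index_sets=[(f.train_idx, f.test_idx) for f in folds],
        fold_pred_events=pred_events,
        importances=importance(bundles),
        aggregate=aggregate,
    )


def _cohort_training_arrays(pdatas: list[ParticipantData], pad_s: float):
    """Concatenated peri-ictal rows of several participants (train-time)."""
    frames, valids, ys = [], [], []
    for pd_ in pdatas:
        split = extract_periictal(pd_.grid, pd_.annotations, pad_s=pad_s, guard_s=0.0)
        frames.append(pd_.grid.features.iloc[split.train_idx])
        valids.append(pd_.grid.valid.iloc[split.train_idx])
        ys.append(pd_.labels.labels[split.train_idx])
    X_df = pd.concat(frames, ignore_index=True)
    v_df = pd.concat(valids, ignore_index=True)
    y = np.concatenate(ys)
    norm = zscore_fit(X_df, v_df)
    return zscore_apply(norm, X_df, v_df), y, norm


def _evaluate_whole_participant(
    pdata: ParticipantData, bundle: ModelBundle, margin_s: float
) -> ScoreReport:
    X = zscore_apply(bundle.norm, pdata.grid.features, pdata.grid.valid)
    pred = bundle.ensemble.predict(X).astype(int)
    none_valid = ~pdata.grid.valid.to_numpy(dtype=bool).any(axis=1)
    pred[none_valid] = 0
    smoothed = smooth_series(pred, pdata.grid.grid_times)
    events = to_events(smoothed, pdata.grid.grid_times)
    truth = EventSet([(a.onset, a.offset) for a in pdata.annotations])
    return score_events(truth, events, pdata.recording, margin_s)


def run_inter_subject(
    train_cohort: list[ParticipantData],
    test_cohort: list[ParticipantData],
    param_grid: list[GTBMParams],
    pad_s: float = 600.0,
    margin_s: float = MATCH_MARGIN_S,
    seed: int = 0,
) -> InterSubjectResult:
    """Leave-one-participant-out optimization and out-of-sample test.

    Hyperparameters are selected by LOPO over the training cohort (each
    training participant held out once as a whole-recording validation set;
    mean fold scores pick the winner).  The final model is trained on all
    peri-ictal data of the training cohort and applied to the complete
    recordings of the test cohort.
    """
    if len(train_cohort) < 2:
        raise ValueError("train cohort needs at least 2 participants")
    train_ids = {p.participant_id for p in train_cohort}
    overlap = train_ids & {p.participant_id for p in test_cohort}
    if overlap:
        raise ValueError(f"participants in both cohorts: {sorted(overlap)}")

    cache: dict[tuple, tuple] = {}

    def eval_fn(params: GTBMParams, held_out: ParticipantData) -> tuple[float, float]:
        others = [p for p in train_cohort if p.participant_id != held_out.participant_id]
        key = held_out.participant_id
        if key not in cache:
            cache[key] = _cohort_training_arrays(others, pad_s)
        X, y, norm = cache[key]
        bundle = train(X, y, params, norm, seed=seed)
        report = _evaluate_whole_participant(held_out, bundle, margin_s)
        return report.sensitivity, report.fp

    best, table = grid_search(train_cohort, param_grid, eval_fn)

    lopo_reports = {}
    for held_out in train_cohort:
        X, y, norm = cache[held_out.participant_id]
        bundle = train(X, y, best, norm, seed=seed)
        lopo_reports[held_out.participant_id] = _evaluate_whole_participant(
            held_out, bundle, margin_s
        )
    X, y, norm = _cohort_training_arrays(train_cohort, pad_s)
    final = train(X, y, best, norm, seed=seed)
    test_reports = {
        p.participant_id: _evaluate_whole_participant(p, final, margin_s)
        for p in test_cohort
    }

    def _agg(reports: dict[str, ScoreReport]) -> dict:
        tps = [r.tp for r in reports.values()]
        totals = [r.tp + r.fn for r in reports.values()]
        return {
            "pooled_sensitivity": pooled_sensitivity(tps, totals),
            "mean_sensitivity": mean_fold_sensitivity(tps, totals),
            "total_fp": int(np.sum([r.fp for r in reports.values()])),
            "mean_far24": float(np.mean([r.far24 for r in reports.values()])),
            "mean_ppv": float(np.mean([r.ppv for r in reports.values()])),
        }

    return InterSubjectResult(
        best_params=best,
        score_table=table,
        lopo_reports=lopo_reports,
        test_reports=test_reports,
        final_bundle=final,
        importances=importance(final),
        aggregate={"lopo": _agg(lopo_reports), "test": _agg(test_reports)},
    )


def permutation_null(
    pred: EventSet,
    truth: EventSet,
    recording: MultimodalRecording,
    n_reps: int = 100,
    margin_s: float = MATCH_MARGIN_S,
    seed: int = 0,
) -> np.ndarray:
    """TP counts when the truth events are placed uniformly at random.

    The null model preserves event durations and places each truth event
    uniformly inside the recorded segments; the returned distribution is the
    reference for "no systematic detection" negative controls.
    """
    rng = np.random.default_rng(seed)
    durations = [e - s for s, e in truth]
    segs = [(s.start_time, s.end_time) for s in recording.segments]
    weights = np.array([e - s for s, e in segs])
    weights = weights / weights.sum()
    counts = np.empty(n_reps, dtype=int)
    for r in range(n_reps):
        placed = []
        for d in durations:
            si = rng.choice(len(segs), p=weights)
            s0, e0 = segs[si]
            start = rng.uniform(s0, max(s0, e0 - d))
            placed.append((start, start + d))
        placed.sort()
        # overlapping placements are legal for the null: score directly
        tp = 0
        for ts, te in placed:
            lo, hi = ts - margin_s, te + margin_s
            if any(ps <= hi and pe >= lo for ps, pe in pred):
                tp += 1
        counts[r] = tp
    return counts
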