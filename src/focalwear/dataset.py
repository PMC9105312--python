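"""Feature-grid assembly, labels, peri-ictal training sets, normalization
and cohort selection filters.

The 11-dimensional feature grid combines the three modality series on a
shared 2-s grid.  Training sets for the detector are *peri-ictal*: the
interval from 10 min before seizure onset to 10 min after offset, so the
model sees each seizure against its immediate surround; the heavily
imbalanced full recording is only ever seen at test time.  Standardization
parameters (per-feature mean and standard deviation) are fitted on training
rows only and stored, never re-fitted on test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features_acc, features_bvp, features_eda
from .grid import GRID_STEP_S
from .signal_model import MultimodalRecording, SeizureAnnotation, recording_hours

__all__ = [
    "FEATURE_NAMES",
    "FeatureGrid",
    "LabelSeries",
    "NormalizationParams",
    "SelectionCriteria",
    "PeriIctalSplit",
    "ParticipantData",
    "build_feature_grid",
    "make_labels",
    "extract_periictal",
    "zscore_fit",
    "zscore_apply",
    "filter_seizures",
    "filter_recordings",
    "eda_quality_flags",
    "prepare_participant",
]

#: Canonical feature order: 4 ACC (RQA), 3 EDA, 4 BVP.
FEATURE_NAMES = (
    features_acc.ACC_FEATURE_NAMES
    + features_eda.EDA_FEATURE_NAMES
    + features_bvp.BVP_FEATURE_NAMES
)

PERIICTAL_PAD_S = 600.0
#: Guard band purged from test sets around training spans, so feature windows
#: straddling the train/test boundary cannot leak (configurable).
TEST_GUARD_S = 600.0


@dataclass
class FeatureGrid:
    """11 named feature streams on the 2-s grid with per-stream validity."""

    participant_id: str
    grid_times: np.ndarray
    features: pd.DataFrame  # columns = FEATURE_NAMES
    valid: pd.DataFrame  # boolean, same shape

    def __post_init__(self) -> None:
        if tuple(self.features.columns) != tuple(FEATURE_NAMES):
            raise ValueError("feature columns must match the canonical 11-name list")

    @property
    def n_points(self) -> int:
        return int(self.grid_times.shape[0])

    def to_frame(self) -> pd.DataFrame:
        """Columnar export: time, features, validity flags."""
        out = pd.DataFrame({"grid_time": self.grid_times})
        out = pd.concat([out, self.features.reset_index(drop=True)], axis=1)
        for name in FEATURE_NAMES:
            out[f"valid_{name}"] = self.valid[name].to_numpy()
        return out


@dataclass
class LabelSeries:
    grid_times: np.ndarray
    labels: np.ndarray  # binary int, 1 = ictal

    def __post_init__(self) -> None:
        if self.grid_times.shape[0] != self.labels.shape[0]:
            raise ValueError("labels must align with grid times")


@dataclass
class NormalizationParams:
    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray


@dataclass
class SelectionCriteria:
    """Cohort inclusion rules: recordings of at least 24 h; seizures of
    10 s to 10 min; usable peri-ictal EDA."""

    min_recording_hours: float = 24.0
    seizure_dur_bounds: tuple[float, float] = (10.0, 600.0)
    eda_flat_threshold_us: float = 0.01
    eda_flat_fraction: float = 0.5
    eda_unstable_slope_us_per_s: float = 5.0
    eda_unstable_max_epochs: int = 10
    apply_eda_quality: bool = False


@dataclass
class PeriIctalSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_spans: list[tuple[float, float]]


@dataclass
class ParticipantData:
    """Everything the evaluation harnesses need for one participant."""

    participant_id: str
    recording: MultimodalRecording
    grid: FeatureGrid
    labels: LabelSeries
    annotations: list[SeizureAnnotation]  # retained seizures, sorted by onset
    exclusion_log: list[dict] = field(default_factory=list)

    @property
    def hours(self) -> float:
        return recording_hours(self.recording)


def build_feature_grid(recording: MultimodalRecording, **feature_kwargs) -> FeatureGrid:
    """Compute all three modality series on the shared grid.

    ``feature_kwargs`` may carry ``acc``, ``eda`` and ``bvp`` dicts of
    module-level options (radius fraction, derivative threshold, ...).
    """
    t_acc, f_acc, m_acc = features_acc.acc_feature_series(
        recording, **feature_kwargs.get("acc", {})
    )
    t_eda, f_eda, m_eda = features_eda.eda_feature_series(
        recording, **feature_kwargs.get("eda", {})
    )
    t_bvp, f_bvp, m_bvp = features_bvp.bvp_feature_series(
        recording, **feature_kwargs.get("bvp", {})
    )
    if not (np.array_equal(t_acc, t_eda) and np.array_equal(t_acc, t_bvp)):
        raise AssertionError("modality series disagree on the grid")
    features = {**f_acc, **f_eda, **f_bvp}
    masks = {**m_acc, **m_eda, **m_bvp}
    return FeatureGrid(
        participant_id=recording.participant_id,
        grid_times=t_acc,
        features=pd.DataFrame({n: features[n] for n in FEATURE_NAMES}),
        valid=pd.DataFrame({n: masks[n] for n in FEATURE_NAMES}),
    )


def make_labels(annotations: list[SeizureAnnotation], grid: FeatureGrid) -> LabelSeries:
    """Binary ictal labels: 1 where the half-open 2-s interval [t, t+2)
    overlaps the closed seizure interval [onset, offset] of any annotation."""
    t = grid.grid_times
    labels = np.zeros(t.shape[0], dtype=int)
    for a in annotations:
        labels[(t <= a.offset) & (t + GRID_STEP_S > a.onset)] = 1
    return LabelSeries(grid_times=t, labels=labels)


def _union_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def extract_periictal(
    grid: FeatureGrid,
    annotations: list[SeizureAnnotation],
    pad_s: float = PERIICTAL_PAD_S,
    guard_s: float = TEST_GUARD_S,
) -> PeriIctalSplit:
    """Peri-ictal training rows and the disjoint test-row complement.

    Training rows are the union of ``[onset - pad, offset + pad]`` over the
    given seizures.  Test rows are everything else, minus an additional
    ``guard_s`` band around each training span so that no test feature
    window overlaps training data.  The two index sets are disjoint by
    construction.
    """
    t = grid.grid_times
    spans = _union_intervals([(a.onset - pad_s, a.offset + pad_s) for a in annotations])
    in_train = np.zeros(t.shape[0], dtype=bool)
    in_guard = np.zeros(t.shape[0], dtype=bool)
    for a, b in spans:
        # positive-measure overlap: a span of 1260 s covers exactly 630 rows
        in_train |= (t < b) & (t + GRID_STEP_S > a)
        in_guard |= (t <= b + guard_s) & (t + GRID_STEP_S > a - guard_s)
    return PeriIctalSplit(
        train_idx=np.flatnonzero(in_train),
        test_idx=np.flatnonzero(~in_guard),
        train_spans=spans,
    )


def zscore_fit(
    X: pd.DataFrame, valid: pd.DataFrame | None = None
) -> NormalizationParams:
    """Per-feature mean/sd fitted on (valid) training rows only.

    Raises on zero-variance columns, naming the offending feature: a
    constant feature cannot be standardized and would be silently useless.
    """
    names = tuple(X.columns)
    center = np.empty(len(names))
    scale = np.empty(len(names))
    for i, name in enumerate(names):
        col = X[name].to_numpy(dtype=float)
        if valid is not None:
            col = col[valid[name].to_numpy(dtype=bool)]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValueError(f"feature {name!r} has no valid training values")
        center[i] = col.mean()
        scale[i] = col.std(ddof=0)
        if scale[i] <= 0:
            raise ValueError(f"feature {name!r} is constant on the training rows")
    return NormalizationParams(feature_names=names, center=center, scale=scale)


def zscore_apply(
    params: NormalizationParams,
    X: pd.DataFrame,
    valid: pd.DataFrame | None = None,
    impute_masked: bool = True,
) -> np.ndarray:
    """Standardize with *stored* parameters (never re-fitted on test data).

    Columns are aligned by name.  Masked or non-finite entries are imputed
    as 0 after standardization — the training mean, the least informative
    value for a tree split.
    """
    cols = []
    for i, name in enumerate(params.feature_names):
        if name not in X.columns:
            raise KeyError(f"feature {name!r} missing from input")
        col = (X[name].to_numpy(dtype=float) - params.center[i]) / params.scale[i]
        if impute_masked:
            bad = ~np.isfinite(col)
            if valid is not None:
                bad |= ~valid[name].to_numpy(dtype=bool)
            col = np.where(bad, 0.0, col)
        cols.append(col)
    return np.column_stack(cols)


def filter_seizures(
    annotations: list[SeizureAnnotation], criteria: SelectionCriteria | None = None
) -> tuple[list[SeizureAnnotation], list[dict]]:
    """Retain seizures within the duration bounds; log each exclusion."""
    criteria = criteria or SelectionCriteria()
    lo, hi = criteria.seizure_dur_bounds
    kept, log = [], []
    for a in annotations:
        if a.duration < lo:
            log.append({"seizure_id": a.seizure_id, "rule": "duration_below_min",
                        "duration_s": a.duration})
        elif a.duration > hi:
            log.append({"seizure_id": a.seizure_id, "rule": "duration_above_max",
                        "duration_s": a.duration})
        else:
            kept.append(a)
    return kept, log


def filter_recordings(
    recordings: list[MultimodalRecording], criteria: SelectionCriteria | None = None
) -> tuple[list[MultimodalRecording], list[dict]]:
    """Retain recordings with at least the minimum recorded hours."""
    criteria = criteria or SelectionCriteria()
    kept, log = [], []
    for rec in recordings:
        hours = recording_hours(rec)
        if hours < criteria.min_recording_hours:
            log.append({"participant_id": rec.participant_id,
                        "rule": "recording_below_min_hours", "hours": hours})
        else:
            kept.append(rec)
    return kept, log


def eda_quality_flags(
    recording: MultimodalRecording,
    seizure: SeizureAnnotation,
    criteria: SelectionCriteria | None = None,
    pad_s: float = PERIICTAL_PAD_S,
) -> dict[str, bool]:
    """Numeric stand-ins for the visual peri-ictal EDA quality screen.

    ``flat_zero``: electrode-contact loss — at least half the peri-ictal EDA
    below 0.01 uS.  ``unstable``: loosely fitting device — more than 10
    2-s epochs whose maximum absolute slope exceeds 5 uS/s.  Both thresholds
    are configurable approximations of a visual check.
    """
    criteria = criteria or SelectionCriteria()
    lo, hi = seizure.onset - pad_s, seizure.offset + pad_s
    vals, slopes = [], []
    for seg in recording.segments:
        if "EDA" not in seg.channels:
            continue
        ch = seg.eda()
        t = ch.times()
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 2:
            continue
        x = ch.samples[sel]
        vals.append(x)
        slopes.append(np.abs(np.diff(x)) * ch.sample_rate)
    if not vals:
        return {"flat_zero": True, "unstable": False}
    x = np.concatenate(vals)
    d = np.concatenate(slopes) if slopes else np.empty(0)
    flat = float(np.mean(x < criteria.eda_flat_threshold_us)) >= criteria.eda_flat_fraction
    # per 2-s epoch: does any sample-to-sample slope exceed the bound
    epoch = int(round(GRID_STEP_S * 4.0))
    n_epochs = d.shape[0] // epoch
    exceed = 0
    if n_epochs:
        exceed = int((d[: n_epochs * epoch].reshape(n_epochs, epoch)
                      > criteria.eda_unstable_slope_us_per_s).any(axis=1).sum())
    unstable = exceed > criteria.eda_unstable_max_epochs
    return {"flat_zero": bool(flat), "unstable": bool(unstable)}


def prepare_participant(
    recording: MultimodalRecording,
    annotations: list[SeizureAnnotation],
    criteria: SelectionCriteria | None = None,
    **feature_kwargs,
) -> ParticipantData:
    """Apply seizure selection, build the feature grid and labels."""
    criteria = criteria or SelectionCriteria()
    kept, log = filter_seizures(annotations, criteria)
    if criteria.apply_eda_quality:
        retained = []
        for a in kept:
            flags = eda_quality_flags(recording, a, criteria)
            if flags["flat_zero"] or flags["unstable"]:
                log.append({"seizure_id": a.seizure_id, "rule": "eda_quality",
                            **flags, "note": "numeric stand-in for visual screen"})
            else:
                retained.append(a)
        kept = retained
    grid = build_feature_grid(recording, **feature_kwargs)
    labels = make_labels(kept, grid)
    return ParticipantData(
        participant_id=recording.participant_id,
        recording=recording,
        grid=grid,
        labels=labels,
        annotations=sorted(kept, key=lambda a: a.onset),
        exclusion_log=log,
    )
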