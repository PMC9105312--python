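"""Domain model and on-disk formats for multimodal wrist-wearable recordings.

A recording is a sequence of non-overlapping *segments* (continuous streaming
sessions; the gaps between them correspond to device swaps or streaming loss).
Each segment carries one channel per modality: 3-axis accelerometry (ACC,
32 Hz, in g), electrodermal activity (EDA, 4 Hz, in microsiemens), blood
volume pulse (BVP, 64 Hz, arbitrary units) and optionally skin temperature
(TEMP, 4 Hz, degrees Celsius).

The session directory layout mirrors the common research-wearable CSV export
dialect: one CSV per channel whose first row is the epoch start time (UTC
seconds), second row the sample rate in Hz, and remaining rows the samples
(three columns for ACC).  ACC is stored on disk in raw counts of 1/64 g and
converted to g at read time.  A ``meta.json`` sidecar holds participant id,
wrist side and the local-time UTC offset needed for night-window scoring.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TimeSeriesChannel",
    "Segment",
    "MultimodalRecording",
    "SeizureAnnotation",
    "ChannelMissingError",
    "SessionFormatError",
    "AnnotationError",
    "read_session",
    "write_session",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "recording_hours",
    "CHANNEL_RATES",
    "MANDATORY_CHANNELS",
    "ACC_COUNTS_PER_G",
]

#: Native sample rates of the supported channels (Hz).
CHANNEL_RATES = {"ACC": 32.0, "EDA": 4.0, "BVP": 64.0, "TEMP": 4.0}
MANDATORY_CHANNELS = ("ACC", "EDA", "BVP")
#: On-disk ACC unit: raw counts of 1/64 g (device default; configurable at read).
ACC_COUNTS_PER_G = 64.0

MOTOR_FLAGS = ("tonic", "clonic", "automatism", "hyperkinetic")


class ChannelMissingError(ValueError):
    """A mandatory channel file is absent from a session directory."""


class SessionFormatError(ValueError):
    """A session CSV header or payload is malformed."""


class AnnotationError(ValueError):
    """An annotation row violates its invariants (e.g. offset <= onset)."""


@dataclass
class TimeSeriesChannel:
    """One uniformly sampled channel of a session segment.

    ``samples`` is 1-D for scalar channels and ``(n, 3)`` for ACC.
    """

    name: str
    start_time: float
    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration(self) -> float:
        """Span covered by the samples in seconds (n / rate)."""
        return self.n_samples / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class Segment:
    """One contiguous streaming session; all channels share its start time."""

    start_time: float
    channels: dict[str, TimeSeriesChannel] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        if not self.channels:
            return 0.0
        return max(ch.duration for ch in self.channels.values())

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def acc(self) -> TimeSeriesChannel:
        return self.channels["ACC"]

    def eda(self) -> TimeSeriesChannel:
        return self.channels["EDA"]

    def bvp(self) -> TimeSeriesChannel:
        return self.channels["BVP"]


@dataclass
class MultimodalRecording:
    """All segments of one participant, sorted and non-overlapping in time."""

    participant_id: str
    segments: list[Segment] = field(default_factory=list)
    device_wrist: str = "unknown"
    utc_offset_hours: float = 0.0

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.start_time)
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_time < a.end_time - 1e-9:
                raise ValueError(
                    f"segments overlap: [{a.start_time}, {a.end_time}] and "
                    f"[{b.start_time}, {b.end_time}]"
                )

    @property
    def start_time(self) -> float:
        return self.segments[0].start_time if self.segments else float("nan")

    @property
    def end_time(self) -> float:
        return self.segments[-1].end_time if self.segments else float("nan")


@dataclass
class SeizureAnnotation:
    """Expert-labeled ictal interval with semiology metadata.

    ``seizure_side_matches_device`` is True/False when laterality is known
    and None for unknown.
    """

    seizure_id: str
    onset: float
    offset: float
    motor_flags: frozenset[str] = frozenset()
    tachycardia: bool = False
    vigilance: str = "awake"
    seizure_side_matches_device: bool | None = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise AnnotationError(
                f"seizure {self.seizure_id}: offset ({self.offset}) must exceed "
                f"onset ({self.onset})"
            )
        bad = set(self.motor_flags) - set(MOTOR_FLAGS)
        if bad:
            raise AnnotationError(f"unknown motor flags: {sorted(bad)}")
        self.motor_flags = frozenset(self.motor_flags)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


# ---------------------------------------------------------------------------
# Session directory I/O


def _read_channel_csv(path: Path, name: str, n_cols: int) -> TimeSeriesChannel:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            start_row = next(reader)
            rate_row = next(reader)
            start = float(start_row[0])
            rate = float(rate_row[0])
        except (StopIteration, ValueError, IndexError) as exc:
            raise SessionFormatError(f"{path}: malformed header rows") from exc
        try:
            data = [[float(v) for v in row[:n_cols]] for row in reader if row]
        except ValueError as exc:
            raise SessionFormatError(f"{path}: non-numeric sample row") from exc
    samples = np.asarray(data, dtype=float)
    if n_cols == 1:
        samples = samples.reshape(-1)
    elif samples.size == 0:
        samples = samples.reshape(0, n_cols)
    return TimeSeriesChannel(name=name, start_time=start, sample_rate=rate, samples=samples)


def read_session(directory: str | Path, acc_counts_per_g: float = ACC_COUNTS_PER_G) -> Segment:
    """Read one session directory into a :class:`Segment`.

    ACC raw counts are converted to g using ``acc_counts_per_g`` (device
    default 64 counts/g; pass 1.0 for data already stored in g).

    Raises :class:`ChannelMissingError` if ACC, EDA or BVP is absent.
    """
    directory = Path(directory)
    channels: dict[str, TimeSeriesChannel] = {}
    for name in ("ACC", "EDA", "BVP", "TEMP"):
        path = directory / f"{name}.csv"
        if not path.exists():
            if name in MANDATORY_CHANNELS:
                raise ChannelMissingError(f"mandatory channel file missing: {path}")
            continue
        n_cols = 3 if name == "ACC" else 1
        ch = _read_channel_csv(path, name, n_cols)
        if name == "ACC":
            ch.samples = ch.samples / acc_counts_per_g
        channels[name] = ch
    starts = {ch.start_time for ch in channels.values()}
    if len(starts) != 1:
        raise SessionFormatError(
            f"{directory}: channel start times disagree: {sorted(starts)}"
        )
    return Segment(start_time=starts.pop(), channels=channels)


def _fmt(x: float) -> str:
    # repr round-trips doubles exactly; integers print without exponent noise
    if float(x).is_integer() and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def write_session(
    directory: str | Path, segment: Segment, acc_counts_per_g: float = ACC_COUNTS_PER_G
) -> None:
    """Write a segment as a session directory (inverse of :func:`read_session`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, ch in segment.channels.items():
        path = directory / f"{name}.csv"
        samples = ch.samples
        if name == "ACC":
            samples = samples * acc_counts_per_g
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([_fmt(ch.start_time)])
            writer.writerow([_fmt(ch.sample_rate)])
            if samples.ndim == 1:
                for v in samples:
                    writer.writerow([_fmt(v)])
            else:
                for row in samples:
                    writer.writerow([_fmt(v) for v in row])


def write_recording(root: str | Path, recording: MultimodalRecording) -> None:
    """Write a recording as ``meta.json`` plus one session dir per segment."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    meta = {
        "participant_id": recording.participant_id,
        "wrist": recording.device_wrist,
        "utc_offset_hours": recording.utc_offset_hours,
        "n_segments": len(recording.segments),
    }
    (root / "meta.json").write_text(json.dumps(meta, indent=2))
    for i, seg in enumerate(recording.segments):
        write_session(root / f"segment_{i:03d}", seg)


def read_recording(root: str | Path) -> MultimodalRecording:
    """Read a recording directory written by :func:`write_recording`."""
    root = Path(root)
    meta = json.loads((root / "meta.json").read_text())
    seg_dirs = sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("segment_"))
    segments = [read_session(d) for d in seg_dirs]
    return MultimodalRecording(
        participant_id=meta["participant_id"],
        segments=segments,
        device_wrist=meta.get("wrist", "unknown"),
        utc_offset_hours=float(meta.get("utc_offset_hours", 0.0)),
    )


# ---------------------------------------------------------------------------
# Annotation I/O

_ANN_COLUMNS = [
    "seizure_id",
    "onset_epoch_s",
    "offset_epoch_s",
    "motor_flags",
    "tachycardia",
    "vigilance",
    "side_matches_device",
]


def read_annotations(path: str | Path) -> list[SeizureAnnotation]:
    """Read seizure annotations from CSV, sorted by onset.

    Columns: ``seizure_id,onset_epoch_s,offset_epoch_s,motor_flags``
    (semicolon-joined), ``tachycardia,vigilance,side_matches_device``
    (true/false/unknown).
    """
    out: list[SeizureAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            flags = frozenset(f for f in (row["motor_flags"] or "").split(";") if f)
            side_raw = (row.get("side_matches_device") or "unknown").strip().lower()
            side = None if side_raw in ("", "unknown") else side_raw == "true"
            out.append(
                SeizureAnnotation(
                    seizure_id=row["seizure_id"],
                    onset=float(row["onset_epoch_s"]),
                    offset=float(row["offset_epoch_s"]),
                    motor_flags=flags,
                    tachycardia=(row.get("tachycardia") or "false").strip().lower() == "true",
                    vigilance=(row.get("vigilance") or "awake").strip().lower(),
                    seizure_side_matches_device=side,
                )
            )
    return sorted(out, key=lambda a: a.onset)


def write_annotations(path: str | Path, annotations: list[SeizureAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANN_COLUMNS)
        for a in annotations:
            side = "unknown" if a.seizure_side_matches_device is None else str(
                a.seizure_side_matches_device
            ).lower()
            writer.writerow(
                [
                    a.seizure_id,
                    _fmt(a.onset),
                    _fmt(a.offset),
                    ";".join(sorted(a.motor_flags)),
                    str(a.tachycardia).lower(),
                    a.vigilance,
                    side,
                ]
            )


def recording_hours(recording: MultimodalRecording) -> float:
    """Hours of data actually recorded: sum of segment durations, gaps excluded.

    This is the denominator of the 24-h false alarm rate.
    """
    return sum(seg.duration for seg in recording.segments) / 3600.0
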