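"""The shared 2-s feature grid.

All features, labels and predictions live on a uniform grid of 2-s intervals.
Each grid point ``t`` stands for the half-open interval ``[t, t+2)``; grids
are built per segment (they never bridge recording gaps) and then
concatenated, so consecutive grid times may jump across segment boundaries.
"""

from __future__ import annotations

import numpy as np

from .signal_model import MultimodalRecording, Segment

GRID_STEP_S = 2.0

__all__ = ["GRID_STEP_S", "segment_grid_times", "recording_grid_times"]


def segment_grid_times(segment: Segment, step: float = GRID_STEP_S) -> np.ndarray:
    """Grid times for one segment: start, start+step, ... while the full
    interval ``[t, t+step)`` fits inside the segment."""
    n = int(np.floor(segment.duration / step + 1e-9))
    return segment.start_time + step * np.arange(n)


def recording_grid_times(
    recording: MultimodalRecording, step: float = GRID_STEP_S
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated grid times and the segment index of every grid point."""
    times, seg_idx = [], []
    for i, seg in enumerate(recording.segments):
        t = segment_grid_times(seg, step)
        times.append(t)
        seg_idx.append(np.full(t.shape, i, dtype=int))
    if not times:
        return np.empty(0), np.empty(0, dtype=int)
    return np.concatenate(times), np.concatenate(seg_idx)
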