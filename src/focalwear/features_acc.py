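"""Recurrence-quantification features from 3-axis accelerometry.

Movement structure is summarized by recurrence quantification analysis (RQA)
of 10-s sliding windows of the raw 3-axis signal, emitted every 2 s.  The
recurrence matrix marks pairs of time points whose 3-axis state vectors lie
within a distance threshold (the *radius*); rhythmic ictal movement (clonic
jerking, tonic tremor) produces long diagonal line structures, while
arbitrary daily movement does not.

Four measures are computed from the thresholded matrix, with the line of
identity (main diagonal) excluded throughout:

- recurrence rate ``RR``   — density of recurrent points, ``R / (N^2 - N)``;
- determinism ``DET``      — fraction of recurrent points lying on diagonal
  lines of length >= ``l_min``;
- average line length ``L``— mean length of those diagonal lines (NaN
  sentinel when there are none);
- Shannon entropy ``ENTR`` — entropy (nats) of the diagonal line length
  distribution for lines >= ``l_min``.

The phase space is the raw 3-axis state vector by default (the three axes
already span a 3-D space); a time-delay embedding of the magnitude signal is
available as an alternative.  The radius adapts per window to a fraction of
the maximum pairwise distance, keeping RR comparable across activity levels;
a fixed absolute radius can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .grid import GRID_STEP_S, recording_grid_times
from .signal_model import MultimodalRecording

__all__ = [
    "RecurrencePlot",
    "RQAMeasures",
    "recurrence_matrix",
    "rqa",
    "magnitude_embedding",
    "acc_feature_series",
    "ACC_FEATURE_NAMES",
]

ACC_FEATURE_NAMES = ("f_acc_det", "f_acc_entr", "f_acc_len", "f_acc_rr")

WINDOW_SPAN_S = 10.0
DEFAULT_RADIUS_FRACTION = 0.1
DEFAULT_L_MIN = 2
COVERAGE_TOLERANCE = 0.95


@dataclass
class RecurrencePlot:
    matrix: np.ndarray  # N x N boolean, symmetric, diagonal all True
    radius: float
    window_span: float = WINDOW_SPAN_S


@dataclass
class RQAMeasures:
    determinism: float
    shannon_entropy: float
    avg_diag_len: float  # NaN sentinel when no line of length >= l_min exists
    recurrence_rate: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.determinism,
            self.shannon_entropy,
            self.avg_diag_len,
            self.recurrence_rate,
        )


def magnitude_embedding(acc_window: np.ndarray, dim: int = 3, delay: int = 4) -> np.ndarray:
    """Time-delay embedding of the acceleration magnitude signal.

    Alternative phase space to the raw 3-axis vectors; returns an
    ``(N - (dim-1)*delay, dim)`` state array.
    """
    mag = np.linalg.norm(np.atleast_2d(acc_window), axis=-1)
    n = mag.shape[0] - (dim - 1) * delay
    if n <= 0:
        raise ValueError("window too short for requested embedding")
    return np.stack([mag[i * delay : i * delay + n] for i in range(dim)], axis=1)


def recurrence_matrix(
    acc_window: np.ndarray,
    radius_fraction: float = DEFAULT_RADIUS_FRACTION,
    radius: float | None = None,
) -> RecurrencePlot:
    """Threshold the pairwise Euclidean distances of a state-vector window.

    ``acc_window`` is ``(N, d)`` (rows are state vectors).  By default the
    radius is ``radius_fraction`` times the maximum pairwise distance in the
    window; pass ``radius`` for a fixed absolute threshold.
    """
    x = np.atleast_2d(np.asarray(acc_window, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("recurrence matrix needs at least 2 state vectors")
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    if radius is None:
        if not 0 < radius_fraction <= 1:
            raise ValueError("radius_fraction must be in (0, 1]")
        radius = radius_fraction * dist.max()
    return RecurrencePlot(matrix=dist <= radius, radius=float(radius))


def _diagonal_line_histogram(matrix: np.ndarray) -> tuple[int, np.ndarray]:
    """Recurrent point count and diagonal line-length histogram, LOI excluded.

    Lines in both triangles are counted (a symmetric matrix contributes each
    line twice, once per triangle).  Returns ``(n_points, hist)`` with
    ``hist[l]`` the number of maximal diagonal runs of length ``l``.
    """
    m = np.asarray(matrix, dtype=bool)
    n = m.shape[0]
    hist = np.zeros(n + 1, dtype=np.int64)
    n_points = 0
    for k in range(1, n):
        for diag in (np.diagonal(m, k), np.diagonal(m, -k)):
            n_points += int(diag.sum())
            run = 0
            for v in diag:
                if v:
                    run += 1
                elif run:
                    hist[run] += 1
                    run = 0
            if run:
                hist[run] += 1
    return n_points, hist


def rqa(rp: RecurrencePlot | np.ndarray, l_min: int = DEFAULT_L_MIN) -> RQAMeasures:
    """Recurrence quantification measures of a recurrence matrix.

    Degenerate conventions: with no off-diagonal recurrent points RR=0,
    DET=0, ENTR=0 and the average line length is the NaN sentinel.
    """
    matrix = rp.matrix if isinstance(rp, RecurrencePlot) else np.asarray(rp, dtype=bool)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("RQA needs an at least 2x2 matrix")
    n_points, hist = _diagonal_line_histogram(matrix)
    rr = n_points / (n * n - n)
    if n_points == 0:
        return RQAMeasures(0.0, 0.0, float("nan"), 0.0)
    line_counts = hist[l_min:]
    lengths = np.arange(l_min, hist.shape[0])
    n_lines = int(line_counts.sum())
    det = float((lengths * line_counts).sum()) / n_points
    if n_lines == 0:
        return RQAMeasures(det, 0.0, float("nan"), rr)
    avg_len = float((lengths * line_counts).sum()) / n_lines
    p = line_counts[line_counts > 0] / n_lines
    entr = float(-(p * np.log(p)).sum()) + 0.0  # avoid IEEE -0.0
    return RQAMeasures(det, entr, avg_len, rr)


# ---------------------------------------------------------------------------
# Fused per-window kernel for the feature series (distance matrix, threshold
# and diagonal-line scan in one pass; called tens of thousands of times per
# recording hour).


@njit(cache=True, fastmath=True)
def _rqa_series_kernel(
    samples: np.ndarray,  # (n, 3)
    starts: np.ndarray,  # window start sample indices, clipped
    lengths: np.ndarray,  # window lengths in samples
    radius_fraction: float,
    l_min: int,
    out: np.ndarray,  # (n_windows, 4): det, entr, L, rr
) -> None:
    max_n = 0
    for w in range(starts.shape[0]):
        if lengths[w] > max_n:
            max_n = lengths[w]
    d2 = np.empty((max_n, max_n))
    hist = np.empty(max_n + 1, np.int64)
    for w in range(starts.shape[0]):
        s = starts[w]
        n = lengths[w]
        maxd2 = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                dx = samples[s + i, 0] - samples[s + j, 0]
                dy = samples[s + i, 1] - samples[s + j, 1]
                dz = samples[s + i, 2] - samples[s + j, 2]
                v = dx * dx + dy * dy + dz * dz
                d2[i, j] = v
                if v > maxd2:
                    maxd2 = v
        r2 = (radius_fraction * radius_fraction) * maxd2
        npts = 0
        for l in range(n + 1):
            hist[l] = 0
        for k in range(1, n):
            run = 0
            for i in range(n - k):
                if d2[i, i + k] <= r2:
                    npts += 1
                    run += 1
                else:
                    if run > 0:
                        hist[run] += 1
                    run = 0
            if run > 0:
                hist[run] += 1
        npts *= 2  # both triangles of the symmetric matrix
        rr = npts / (n * n - n)
        if npts == 0:
            out[w, 0] = 0.0
            out[w, 1] = 0.0
            out[w, 2] = np.nan
            out[w, 3] = 0.0
            continue
        det_pts = 0
        n_lines = 0
        for l in range(l_min, n + 1):
            det_pts += 2 * l * hist[l]
            n_lines += 2 * hist[l]
        det = det_pts / npts
        if n_lines == 0:
            out[w, 0] = det
            out[w, 1] = 0.0
            out[w, 2] = np.nan
            out[w, 3] = rr
            continue
        avg_len = det_pts / n_lines
        entr = 0.0
        for l in range(l_min, n + 1):
            if hist[l] > 0:
                p = 2 * hist[l] / n_lines
                entr -= p * np.log(p)
        out[w, 0] = det
        out[w, 1] = entr + 0.0  # avoid IEEE -0.0
        out[w, 2] = avg_len
        out[w, 3] = rr


def acc_feature_series(
    recording: MultimodalRecording,
    radius_fraction: float = DEFAULT_RADIUS_FRACTION,
    l_min: int = DEFAULT_L_MIN,
    coverage: float = COVERAGE_TOLERANCE,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """The four RQA feature streams on the 2-s grid.

    For each grid point ``t`` the window is ``[t-5 s, t+5 s]``; windows
    covering less than ``coverage`` of their expected samples (segment edges,
    recording gaps) are masked rather than zero-filled, since missing data
    would otherwise mimic stillness.

    Returns ``(grid_times, features, valid_masks)``.
    """
    grid_times, seg_idx = recording_grid_times(recording)
    n_grid = grid_times.shape[0]
    values = np.full((n_grid, 4), np.nan)
    valid = np.zeros(n_grid, dtype=bool)
    half = WINDOW_SPAN_S / 2.0
    for i, seg in enumerate(recording.segments):
        sel = np.flatnonzero(seg_idx == i)
        if sel.size == 0 or "ACC" not in seg.channels:
            continue
        acc = seg.acc()
        rate = acc.sample_rate
        n_expected = int(round(WINDOW_SPAN_S * rate))
        min_samples = int(np.ceil(coverage * n_expected))
        centers = grid_times[sel]
        start_f = np.round((centers - half - seg.start_time) * rate).astype(np.int64)
        end_f = start_f + n_expected
        starts = np.clip(start_f, 0, acc.n_samples)
        ends = np.clip(end_f, 0, acc.n_samples)
        lengths = ends - starts
        ok = lengths >= max(min_samples, 2)
        if not ok.any():
            continue
        out = np.empty((int(ok.sum()), 4))
        _rqa_series_kernel(
            np.ascontiguousarray(acc.samples),
            starts[ok],
            lengths[ok],
            float(radius_fraction),
            int(l_min),
            out,
        )
        values[sel[ok]] = out
        valid[sel[ok]] = True
    features = {
        "f_acc_det": values[:, 0],
        "f_acc_entr": values[:, 1],
        "f_acc_len": values[:, 2],
        "f_acc_rr": values[:, 3],
    }
    masks = {
        "f_acc_det": valid.copy(),
        "f_acc_entr": valid.copy(),
        # the NaN average-line-length sentinel propagates into the mask
        "f_acc_len": valid & ~np.isnan(values[:, 2]),
        "f_acc_rr": valid.copy(),
    }
    return grid_times, features, masks
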