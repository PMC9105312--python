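"""Electrodermal activity features: tonic level and phasic response rate.

The skin conductance level (SCL) is the 60-s moving mean of the raw EDA
signal — a low-pass view of the slow tonic drift.  The skin conductance
response rate (SCRR) counts phasic responses as excursions of the first
derivative of the smoothed signal above a small positive slope threshold.

Each of the three features is a *difference* between a 5-min feature window
ending at the grid point and the 5-min baseline window immediately before
it, so a seizure-related electrodermal response shows up as a positive
excursion relative to the participant's recent baseline, and any constant
offset in the raw signal cancels exactly:

- ``f_eda_dauc``  — AUC(SCL, [t-300, t]) - AUC(SCL, [t-600, t-300])  (uS*s)
- ``f_eda_dmax``  — max(SCL, feature) - max(SCL, baseline)           (uS)
- ``f_eda_dscrr`` — SCRR(feature) - SCRR(baseline)                   (count)
"""

from __future__ import annotations

import numpy as np

from .grid import recording_grid_times
from .signal_model import MultimodalRecording

__all__ = [
    "scl",
    "scrr",
    "eda_feature_series",
    "EDA_FEATURE_NAMES",
    "DEFAULT_DERIVATIVE_THRESHOLD",
]

EDA_FEATURE_NAMES = ("f_eda_dauc", "f_eda_dmax", "f_eda_dscrr")

SCL_WINDOW_S = 60.0
FEATURE_WINDOW_S = 300.0
#: Slope threshold separating phasic responses from drift (uS/s), applied to
#: the first derivative of the 60-s-smoothed signal.
DEFAULT_DERIVATIVE_THRESHOLD = 0.01


def scl(eda: np.ndarray, sample_rate: float = 4.0, window_s: float = SCL_WINDOW_S) -> np.ndarray:
    """Skin conductance level: centered moving mean, edge-truncated.

    The window shrinks at segment edges instead of padding, so a constant
    signal maps to itself everywhere.
    """
    x = np.asarray(eda, dtype=float)
    n = x.shape[0]
    if n == 0:
        return x.copy()
    half = int(round(window_s * sample_rate / 2))
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half, 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _supra_threshold_runs(deriv: np.ndarray, threshold: float) -> np.ndarray:
    """Indicator of run starts: deriv enters the supra-threshold state."""
    above = deriv > threshold
    starts = above.copy()
    starts[1:] &= ~above[:-1]
    return starts


def scrr(
    smoothed_window: np.ndarray,
    sample_rate: float = 4.0,
    derivative_threshold: float = DEFAULT_DERIVATIVE_THRESHOLD,
) -> int:
    """Count of upward threshold crossings of the first derivative.

    A window that starts already above threshold contributes one count (the
    signal is in a rising phase as the window opens); a constant signal
    contributes zero.
    """
    x = np.asarray(smoothed_window, dtype=float)
    if x.shape[0] < 2:
        return 0
    deriv = np.diff(x) * sample_rate
    return int(_supra_threshold_runs(deriv, derivative_threshold).sum())


def eda_feature_series(
    recording: MultimodalRecording,
    derivative_threshold: float = DEFAULT_DERIVATIVE_THRESHOLD,
    orientation: str = "trailing",
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """The three EDA feature streams on the 2-s grid.

    ``orientation`` selects the window layout relative to the grid point t:

    - ``"trailing"`` (default): feature [t-300, t], baseline [t-600, t-300] —
      baseline precedes the feature window, and the feature is causal.
    - ``"prose"``: feature [t-300, t], baseline [t, t+300] — baseline after
      the point (alternative reading; anticausal).
    - ``"centered"``: feature [t-150, t+150], baseline [t-450, t-150].

    Grid points whose windows are not fully covered by the segment are
    masked (in particular every point less than 10 min after a segment
    start under the default orientation).
    """
    if orientation == "trailing":
        f_off, b_off = (-FEATURE_WINDOW_S, 0.0), (-2 * FEATURE_WINDOW_S, -FEATURE_WINDOW_S)
    elif orientation == "prose":
        f_off, b_off = (-FEATURE_WINDOW_S, 0.0), (0.0, FEATURE_WINDOW_S)
    elif orientation == "centered":
        h = FEATURE_WINDOW_S / 2
        f_off, b_off = (-h, h), (-3 * h, -h)
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")

    grid_times, seg_idx = recording_grid_times(recording)
    n_grid = grid_times.shape[0]
    values = np.full((n_grid, 3), np.nan)
    valid = np.zeros(n_grid, dtype=bool)
    for i, seg in enumerate(recording.segments):
        sel = np.flatnonzero(seg_idx == i)
        if sel.size == 0 or "EDA" not in seg.channels:
            continue
        eda_ch = seg.eda()
        rate = eda_ch.sample_rate
        n = eda_ch.n_samples
        smoothed = scl(eda_ch.samples, rate)
        # cumulative trapezoid -> O(1) AUC per window
        ct = np.concatenate(
            ([0.0], np.cumsum((smoothed[1:] + smoothed[:-1]) / (2.0 * rate)))
        )
        deriv = np.diff(smoothed) * rate
        run_starts = _supra_threshold_runs(deriv, derivative_threshold)
        run_cs = np.concatenate(([0], np.cumsum(run_starts)))
        above = deriv > derivative_threshold

        def window_idx(offsets: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
            t_rel = grid_times[sel] - seg.start_time
            a = np.round((t_rel + offsets[0]) * rate).astype(np.int64)
            b = np.round((t_rel + offsets[1]) * rate).astype(np.int64)
            return a, b

        fa, fb = window_idx(f_off)
        ba, bb = window_idx(b_off)
        ok = (np.minimum(fa, ba) >= 0) & (np.maximum(fb, bb) <= n - 1)
        for j in np.flatnonzero(ok):
            g = sel[j]
            auc_f = ct[fb[j]] - ct[fa[j]]
            auc_b = ct[bb[j]] - ct[ba[j]]
            max_f = smoothed[fa[j] : fb[j] + 1].max()
            max_b = smoothed[ba[j] : bb[j] + 1].max()

            def run_count(a: int, b: int) -> int:
                # runs starting strictly inside (a, b) plus the state at a
                if b <= a:
                    return 0
                inner = int(run_cs[b] - run_cs[a + 1])
                return inner + (1 if above[a] else 0)

            values[g, 0] = auc_f - auc_b
            values[g, 1] = max_f - max_b
            values[g, 2] = run_count(fa[j], fb[j]) - run_count(ba[j], bb[j])
            valid[g] = True
    features = {
        "f_eda_dauc": values[:, 0],
        "f_eda_dmax": values[:, 1],
        "f_eda_dscrr": values[:, 2],
    }
    masks = {name: valid.copy() for name in EDA_FEATURE_NAMES}
    return grid_times, features, masks
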