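"""Blood-volume-pulse features: beat detection, heart rate, signal quality.

The optical pulse waveform dips once per cardiac cycle, so beats are tracked
as local minima of the raw BVP trace, gated by an adaptive prominence
threshold relative to the local signal amplitude.  Inter-beat intervals
(IBIs) pass through a plausibility cascade (absolute range, running-median
deviation gate, short median filter) before being resampled onto the 2-s
grid as an instantaneous heart rate (HR) estimate.

Because wrist PPG is extremely motion-sensitive, a per-window signal quality
index (SQI) accompanies the HR: the normalized Shannon entropy of the power
spectrum in the cardiac band (0.5-5 Hz).  A clean periodic pulse
concentrates power in few bins (SQI near 0); broadband motion artifact
flattens the spectrum (SQI near 1).  The SQI enters the feature set as a
feature in its own right — artifacts are treated as information rather than
discarded.

The four streams on the 2-s grid:

- ``f_bvp_dmaxhr``  — max HR over (t-60, t] minus max HR over (t-120, t-60]
- ``f_bvp_dmeanhr`` — same with window means
- ``f_bvp_sqi``     — spectral-entropy SQI of the 10-s window centered at t
- ``f_bvp_hr``      — the HR estimate at t
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import find_peaks

from .grid import recording_grid_times
from .signal_model import MultimodalRecording, TimeSeriesChannel

__all__ = [
    "BeatSeries",
    "HREstimate",
    "detect_beats",
    "hr_estimate",
    "spectral_entropy_sqi",
    "bvp_feature_series",
    "BVP_FEATURE_NAMES",
]

BVP_FEATURE_NAMES = ("f_bvp_dmaxhr", "f_bvp_dmeanhr", "f_bvp_sqi", "f_bvp_hr")

MIN_BEAT_SEPARATION_S = 0.33  # <= ~180 bpm
PROMINENCE_FRACTION = 0.25  # of the local peak-to-peak amplitude
AMPLITUDE_WINDOW_S = 4.0
HR_RANGE_BPM = (30.0, 180.0)
MEDIAN_DEVIATION_GATE = 0.25
MEDIAN_FILTER_BEATS = 5
VALIDITY_HORIZON_S = 10.0
SQI_WINDOW_S = 10.0
SQI_BAND_HZ = (0.5, 5.0)
HR_FEATURE_WINDOW_S = 60.0
HR_WINDOW_MAX_INVALID = 0.5


@dataclass
class BeatSeries:
    """Detected beat times (epoch seconds, increasing) and their IBIs."""

    beat_times: np.ndarray

    @property
    def ibis(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.shape[0])


@dataclass
class HREstimate:
    """Heart rate (bpm) on the 2-s grid with a validity mask."""

    hr: np.ndarray
    valid: np.ndarray


def detect_beats(
    bvp: np.ndarray | TimeSeriesChannel,
    sample_rate: float = 64.0,
    start_time: float = 0.0,
    prominence_fraction: float = PROMINENCE_FRACTION,
) -> BeatSeries:
    """Track beats as local minima of the raw BVP trace.

    Minima must be separated by at least 0.33 s and have a prominence above
    ``prominence_fraction`` of the local (4-s) peak-to-peak amplitude, so the
    gate adapts to slow amplitude drift.  A flat signal yields no beats.
    """
    if isinstance(bvp, TimeSeriesChannel):
        sample_rate = bvp.sample_rate
        start_time = bvp.start_time
        bvp = bvp.samples
    x = np.asarray(bvp, dtype=float)
    if x.shape[0] < 3:
        return BeatSeries(np.empty(0))
    distance = max(1, int(round(MIN_BEAT_SEPARATION_S * sample_rate)))
    peaks, props = find_peaks(-x, distance=distance, prominence=1e-12)
    if peaks.size == 0:
        return BeatSeries(np.empty(0))
    size = max(2, int(round(AMPLITUDE_WINDOW_S * sample_rate)))
    local_amp = maximum_filter1d(x, size) - minimum_filter1d(x, size)
    keep = props["prominences"] >= np.maximum(prominence_fraction * local_amp[peaks], 1e-12)
    return BeatSeries(start_time + peaks[keep] / sample_rate)


def _filter_ibis(beats: BeatSeries) -> tuple[np.ndarray, np.ndarray]:
    """IBI plausibility cascade; returns (midpoint times, kept IBIs)."""
    ibis = beats.ibis
    mids = (beats.beat_times[:-1] + beats.beat_times[1:]) / 2.0
    lo, hi = 60.0 / HR_RANGE_BPM[1], 60.0 / HR_RANGE_BPM[0]
    in_range = (ibis >= lo) & (ibis <= hi)
    ibis, mids = ibis[in_range], mids[in_range]
    keep = np.ones(ibis.shape[0], dtype=bool)
    # gate against the running median of the last in-range IBIs (isolated
    # artifacts are rejected; genuine sustained rate changes shift the
    # median within a few beats and pass)
    recent: list[float] = []
    for i, v in enumerate(ibis):
        if recent:
            med = float(np.median(recent))
            if abs(v - med) > MEDIAN_DEVIATION_GATE * med:
                keep[i] = False
        recent.append(float(v))
        if len(recent) > MEDIAN_FILTER_BEATS:
            recent.pop(0)
    return mids[keep], ibis[keep]


def hr_estimate(beats: BeatSeries, grid_times: np.ndarray) -> HREstimate:
    """Filtered instantaneous HR interpolated onto the 2-s grid.

    IBIs outside [60/180, 2] s are discarded, IBIs deviating more than 25%
    from the running median are discarded, the HR sequence is median-filtered
    over 5 beats, then linearly interpolated.  Grid points more than 10 s
    from any retained beat midpoint are invalid.
    """
    grid_times = np.asarray(grid_times, dtype=float)
    n = grid_times.shape[0]
    if beats.n_beats < 2:
        return HREstimate(np.full(n, np.nan), np.zeros(n, dtype=bool))
    mids, ibis = _filter_ibis(beats)
    if mids.shape[0] == 0:
        return HREstimate(np.full(n, np.nan), np.zeros(n, dtype=bool))
    hr_inst = 60.0 / ibis
    hr_med = (
        pd.Series(hr_inst).rolling(MEDIAN_FILTER_BEATS, center=True, min_periods=1).median().to_numpy()
    )
    hr = np.interp(grid_times, mids, hr_med)
    # validity horizon: distance to the nearest retained beat midpoint
    pos = np.searchsorted(mids, grid_times)
    dist_right = np.where(pos < mids.shape[0], mids[np.clip(pos, 0, mids.shape[0] - 1)] - grid_times, np.inf)
    dist_left = np.where(pos > 0, grid_times - mids[np.clip(pos - 1, 0, mids.shape[0] - 1)], np.inf)
    valid = np.minimum(dist_left, dist_right) <= VALIDITY_HORIZON_S
    hr[~valid] = np.nan
    return HREstimate(hr, valid)


def spectral_entropy_sqi(
    bvp_window: np.ndarray,
    sample_rate: float = 64.0,
    band: tuple[float, float] = SQI_BAND_HZ,
) -> float:
    """Normalized spectral entropy of one window, restricted to the band.

    ``H = -sum p_k ln p_k / ln K`` over the normalized in-band periodogram.
    An all-zero (powerless) window maps to 1: no evidence of a pulse.
    """
    x = np.asarray(bvp_window, dtype=float)
    psd = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / sample_rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    p = psd[sel]
    total = p.sum()
    if total <= 0 or sel.sum() < 2:
        return 1.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.shape[0]))


def _sqi_series(
    samples: np.ndarray, rate: float, rel_times: np.ndarray, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """SQI of the 10-s window centered at each relative grid time."""
    n = samples.shape[0]
    win = int(round(SQI_WINDOW_S * rate))
    starts = np.round((rel_times - SQI_WINDOW_S / 2) * rate).astype(np.int64)
    ok = (starts >= 0) & (starts + win <= n)
    out = np.full(rel_times.shape[0], np.nan)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return out, ok
    freqs = np.fft.rfftfreq(win, d=1.0 / rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    k = int(sel.sum())
    for c in range(0, idx.size, 4096):
        chunk = idx[c : c + 4096]
        rows = samples[starts[chunk][:, None] + np.arange(win)[None, :]]
        rows = rows - rows.mean(axis=1, keepdims=True)
        psd = np.abs(np.fft.rfft(rows, axis=1)) ** 2
        p = psd[:, sel]
        tot = p.sum(axis=1)
        vals = np.ones(chunk.shape[0])
        pos = tot > 0
        pn = p[pos] / tot[pos, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(pn > 0, pn * np.log(pn), 0.0).sum(axis=1) / np.log(k)
        vals[pos] = ent
        out[chunk] = vals
    return out, ok


def bvp_feature_series(
    recording: MultimodalRecording,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """The four BVP feature streams on the 2-s grid.

    The HR difference features are masked when more than 50% of either 60-s
    window is invalid (or the windows leave the segment); the point SQI and
    HR features keep their own independent masks, since artifact periods are
    themselves informative.
    """
    grid_times, seg_idx = recording_grid_times(recording)
    n_grid = grid_times.shape[0]
    dmax = np.full(n_grid, np.nan)
    dmean = np.full(n_grid, np.nan)
    sqi = np.full(n_grid, np.nan)
    hr_all = np.full(n_grid, np.nan)
    m_d = np.zeros(n_grid, dtype=bool)
    m_sqi = np.zeros(n_grid, dtype=bool)
    m_hr = np.zeros(n_grid, dtype=bool)
    w = int(round(HR_FEATURE_WINDOW_S / 2.0))  # 30 grid points per 60-s window
    for i, seg in enumerate(recording.segments):
        sel = np.flatnonzero(seg_idx == i)
        if sel.size == 0 or "BVP" not in seg.channels:
            continue
        ch = seg.bvp()
        t_seg = grid_times[sel]
        beats = detect_beats(ch)
        est = hr_estimate(beats, t_seg)
        hr_all[sel] = est.hr
        m_hr[sel] = est.valid
        s, ok = _sqi_series(ch.samples, ch.sample_rate, t_seg - seg.start_time, SQI_BAND_HZ)
        sqi[sel] = s
        m_sqi[sel] = ok
        ng = t_seg.shape[0]
        if ng < 2 * w:
            continue
        hr = est.hr
        # feature window (t-60, t] = grid indices [g-w+1, g]; baseline the w before
        swv = np.lib.stride_tricks.sliding_window_view(hr, w)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            wmax = np.nanmax(swv, axis=1)
            wmean = np.nanmean(swv, axis=1)
        n_invalid = np.isnan(swv).sum(axis=1)
        w_ok = n_invalid <= HR_WINDOW_MAX_INVALID * w
        g = np.arange(2 * w - 1, ng)  # first index with both windows inside
        f_i = g - w + 1  # start of feature window -> swv row index
        b_i = g - 2 * w + 1
        ok2 = w_ok[f_i] & w_ok[b_i]
        rows = sel[g[ok2]]
        dmax[rows] = wmax[f_i[ok2]] - wmax[b_i[ok2]]
        dmean[rows] = wmean[f_i[ok2]] - wmean[b_i[ok2]]
        m_d[rows] = True
    features = {
        "f_bvp_dmaxhr": dmax,
        "f_bvp_dmeanhr": dmean,
        "f_bvp_sqi": sqi,
        "f_bvp_hr": hr_all,
    }
    masks = {
        "f_bvp_dmaxhr": m_d.copy(),
        "f_bvp_dmeanhr": m_d.copy(),
        "f_bvp_sqi": m_sqi,
        "f_bvp_hr": m_hr,
    }
    return grid_times, features, masks
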