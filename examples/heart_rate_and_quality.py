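"""Pulse-derived heart rate and signal quality under motion artifact.

Builds a 3-min pulse wave at 72 bpm, corrupts one minute with broadband
artifact (as wrist movement does), and prints the recovered heart rate and
the spectral-entropy signal quality index (SQI) for clean vs corrupted
stretches.
"""

import numpy as np

from focalwear.features_bvp import bvp_feature_series
from focalwear.signal_model import MultimodalRecording, Segment, TimeSeriesChannel

rate, seconds, hr_true = 64.0, 180, 72.0
rng = np.random.default_rng(4)
t = np.arange(int(seconds * rate)) / rate
x = -np.cos(2 * np.pi * (hr_true / 60) * t) + 0.25 * np.sin(4 * np.pi * (hr_true / 60) * t)
x += rng.normal(scale=0.02, size=t.shape)
x[(t >= 60) & (t < 120)] += rng.normal(scale=3.0, size=int(60 * rate))  # movement

seg = Segment(0.0)
seg.channels["BVP"] = TimeSeriesChannel("BVP", 0.0, rate, x)
seg.channels["ACC"] = TimeSeriesChannel("ACC", 0.0, 32.0, np.zeros((seconds * 32, 3)))
seg.channels["EDA"] = TimeSeriesChannel("EDA", 0.0, 4.0, np.full(seconds * 4, 2.0))
rec = MultimodalRecording("HRQ", segments=[seg])

times, feats, masks = bvp_feature_series(rec)
clean = (times > 10) & (times < 55)
dirty = (times > 65) & (times < 115)
hr_clean = np.nanmean(np.where(masks["f_bvp_hr"] & clean, feats["f_bvp_hr"], np.nan))
print(f"true HR 72.0 bpm; recovered over clean stretch: {hr_clean:.1f} bpm")
print(f"SQI clean stretch : {np.nanmean(feats['f_bvp_sqi'][clean]):.2f}  (low = clean pulse)")
print(f"SQI during motion : {np.nanmean(feats['f_bvp_sqi'][dirty]):.2f}  (high = artifact)")
print(
    "\nArtifacts are kept as information: the quality index itself is a model"
    "\nfeature, since pulse quality collapses exactly when the wrist moves."
)
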