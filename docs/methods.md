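# Methods

`focalwear` implements an event-level detection analysis for focal onset
motor seizures from a wrist-worn multimodal wearable (3-axis accelerometry
at 32 Hz, electrodermal activity at 4 Hz, blood volume pulse at 64 Hz).
This note documents the model, its assumptions and parameters, the
numerical choices, what the synthetic data generator does and does not
emulate, and the known limitations.

## Data model

A recording is a list of non-overlapping *segments* — contiguous streaming
sessions separated by gaps from device swaps or streaming loss.  Gaps are
first-class: no feature window, smoothing run or event may bridge one, and
no imputation is performed across them, because silently bridged gaps would
corrupt baselines and mimic stillness.  Recorded hours (the denominator of
the 24-h false alarm rate) sum segment durations only.  Timestamps are
epoch seconds; a per-recording UTC offset converts to local time exactly
once, in the night-window computation.

On disk a session is one CSV per channel (row 1 epoch start, row 2 sample
rate, then samples; three columns for ACC), a layout mirroring the common
research-wearable export dialect, plus a `meta.json` sidecar (participant
id, wrist, UTC offset).  ACC is stored in raw counts of 1/64 g and converted
to g at read time; the conversion factor is an argument because the counts
convention is a device default, not a universal one.

## Feature set

Eleven features are computed at a fixed 2-s cadence, whatever the length of
the underlying window.  All window conventions below are trailing unless
stated; a grid point `t` stands for the half-open interval `[t, t+2)`.

**Movement (4): recurrence quantification.**  Over the 10-s window centered
at `t`, the 3-axis samples are treated as a 3-D phase-space trajectory
(N = 320 states).  The recurrence matrix thresholds pairwise Euclidean
distances at a radius equal to 10% of the window's maximum pairwise
distance — adaptive per window so that recurrence density is comparable
across activity levels; a fixed radius and a delay embedding of the
magnitude signal are available as alternatives.  With the line of identity
excluded and diagonal lines counted in both triangles of the symmetric
matrix, the four measures are: recurrence rate `RR = R/(N²−N)`; determinism
`DET` (fraction of recurrent points on diagonals of length ≥ l_min = 2
samples, the standard convention); average diagonal line length `L` (NaN
sentinel, treated as masked, when no such line exists); and the Shannon
entropy (nats) of the line-length distribution.  Rhythmic clonic jerking and
tonic tremor revisit phase-space states periodically and produce long
diagonals; aperiodic daily movement does not.  Windows with less than 95% of
their expected samples (segment edges) are masked, not zero-filled — missing
accelerometry looks exactly like lying still, which is the failure mode this
rule avoids.

**Electrodermal (3): baselined level and response rate.**  The skin
conductance level (SCL) is the centered 60-s moving mean of the raw signal,
edge-truncated.  Each feature is the difference between the 5-min feature
window `[t−300, t]` and the preceding 5-min baseline `[t−600, t−300]`:
trapezoidal area under the SCL, maximum of the SCL, and the skin conductance
response rate (SCRR) — the number of upward excursions of the SCL first
derivative above +0.01 µS/s, a slope that separates phasic responses from
drift at 4 Hz.  A window already rising as it opens counts one excursion.
Differencing makes all three features exactly invariant to the static
conductance level.  The baseline-before-feature orientation is the causal
choice (features at time `t` use only data before `t`); the anticausal
orientation and a centered variant are available behind a flag.  Points
within 10 min of a segment start are masked (incomplete baseline).

**Pulse (4): heart rate and signal quality.**  Beats are local minima of
the raw BVP trace with ≥ 0.33 s separation and prominence above 25% of the
local (4-s) peak-to-peak amplitude.  Inter-beat intervals pass a
plausibility cascade — absolute range [60/180, 2] s, rejection when
deviating more than 25% from the running median of the last five in-range
intervals, then a 5-beat median filter — before linear interpolation onto
the grid; points more than 10 s from any retained beat are invalid.  The
gate uses the running median of *observed* (in-range) intervals rather than
accepted ones so that a genuine sustained rate change (ictal tachycardia)
shifts the reference within a few beats instead of being rejected forever.
All cascade constants are configuration, not doctrine.  The signal quality
index is the Shannon entropy of the 10-s periodogram restricted to the
cardiac band 0.5–5 Hz, normalized by ln K to [0, 1]; a clean pulse
concentrates power (SQI → 0), broadband motion artifact flattens it
(SQI → 1), and an all-zero window maps to 1 (no evidence of a pulse).  The
two difference features subtract the previous 60-s window's maximum/mean HR
from the current one and are masked when more than half of either window is
invalid; the point HR and SQI features keep independent masks, because
artifact periods are themselves informative and are deliberately not
discarded.

## Detector

The detector is AdaBoost over depth-limited decision trees.  Four
hyperparameters are searched: learning rate, maximum number of weak
learners, maximum tree depth, and a false-positive misclassification cost
`fp_cost ≥ 1` realized as initial observation weights (weight `fp_cost` on
non-seizure samples, 1 on seizure samples; the false-negative cost is fixed
at 1).  Training rows are *peri-ictal only* — the 10 min before onset to
10 min after offset of each training seizure — so the model learns each
seizure against its immediate surround; the massive inter-ictal imbalance
of a full recording is confronted only at test time, and class imbalance is
handled by the cost weight rather than resampling.

Features are standardized by z-score with parameters fitted on training
rows only and stored with the model; test data always re-uses the stored
parameters.  Masked or non-finite entries are imputed as 0 *after*
standardization (the training mean — the least informative value for a tree
split); no validity indicator column is added, keeping the feature count at
eleven.  A constant training column raises an error naming the feature.

The full grid is 5 learning rates × 4 ensemble sizes × 5 depths × 6 costs =
600 combinations; the specific values are this package's choice.  A
desk-scale 24-combination grid (2×2×2×3) is provided for fast end-to-end
runs and is what the examples, acceptance script and end-to-end tests use.
Selection is a strict total order: highest mean fold sensitivity, then
lowest mean false-positive count, then higher learning rate, then fewer
learners (computational economy breaks exact ties), so every score table
has a unique winner.  Feature importances are Gini impurity decreases
averaged over the trees of the ensemble (and over fold models when
summarizing a cross-validation), floored at 0.

## Event scoring

Predictions on the grid are smoothed — gaps of at most 30 s between seizure
labels are filled, then orphan runs shorter than the 6-s event minimum are
removed, in that order — and maximal runs of 6 s to 10 min become events.
A run longer than 10 min is truncated to its first 600 s and counted once;
splitting it instead would manufacture arbitrarily many false positives
from one excursion.  Ground-truth seizures are extended by a 2-min margin
on both sides; any prediction overlapping the extended interval scores the
seizure as one true positive (several overlapping predictions are absorbed,
not penalized), unmatched seizures are false negatives, predictions
matching nothing are false positives.  True negatives are never counted.

Rates: `FAR24 = FP × 24 / recorded hours`; `FARn = FP_night × 8 / nightly
hours recorded`, where an alarm belongs to the night if its *start* falls
in 23:00–07:00 local time (the start is the alarm moment) and nightly hours
count only data actually recorded in that window.  Aggregates over folds or
participants are reported both pooled (total counts over totals) and as
means of per-fold values; the two differ and both are informative.

## Evaluation designs

**Intra-subject (leave-one-seizure-out).**  For a participant with ≥ 3
retained seizures, each fold trains on the peri-ictal surround of all other
seizures and is tested on the entire remaining recording — including the
left-out seizure but excluding every training row and a 10-min guard band
around the training spans, so that no test feature window overlaps training
data.  Train/test index disjointness is asserted on every fold.  One flat
grid search optimizes over the mean fold scores; the winning combination's
per-fold reports are returned.

**Inter-subject (leave-one-participant-out).**  Hyperparameters are
selected by holding each training participant out in turn as a
whole-recording validation set; the final model trains on all peri-ictal
data of the training cohort and is applied to the complete recordings of
disjoint test participants.  Pooled test sensitivity is total detections
over total seizures, not a mean of per-participant ratios.

**Selection filters.**  Recordings of less than 24 h and seizures shorter
than 10 s or longer than 10 min are excluded, with a per-item exclusion
log.  The peri-ictal electrodermal quality screen (a visual check in
clinical practice) is operationalized as two numeric heuristics — flat-zero
(≥ 50% of peri-ictal samples below 0.01 µS: electrode contact loss) and
instability (more than ten 2-s epochs with slopes above 5 µS/s: a loose
device) — both flagged as approximations in the log and off by default.

## Synthetic data

The generator produces the *feature-relevant* structure of in-hospital
wrist recordings, not physiology: circadian background (bout-structured
aperiodic movement while awake at ~10 bouts/h, quiet nights 23:00–07:00),
electrodermal tonic drift with Poisson spontaneous responses (1/min awake,
0.2/min asleep, amplitudes ~0.02–0.5 µS), and a pulse waveform at 55–90 bpm
resting rate — with a circadian dip that eases in and out over ~20 min
rather than stepping at bed/wake time — whose broadband artifact is
proportional to movement intensity, so the SQI degrades exactly when the wrist moves — including
during seizures, which is why heart-rate features are partially masked
peri-ictally, as with real wrist photoplethysmography.  Ictal overlays per
semiology: tonic = sustained 0.35 g offset plus 8–12 Hz low-amplitude
tremor; clonic = 2–5 Hz rhythmic bursts of ~0.7 g; mixed = tonic first
half, clonic second; responder seizures add a 1–2.5 µS electrodermal
response starting 0–20 s after onset and decaying over minutes; ictal
tachycardia ramps the rate by 25–45 bpm from onset; a device contralateral
to the seizure side attenuates ictal movement by a factor 0.3.  Planted
seizure durations are drawn from 20–120 s (inside the 10 s–10 min retention
bounds by construction) and placed one per equal block of the recording
interior, which guarantees feasibility, wide spacing and determinism.
`effect_scale` multiplies every ictal effect; zero yields negative-control
recordings whose labels carry no signal.  All randomness flows from one
master seed through spawned per-participant streams.

The default cohort mirrors a realistic in-hospital study shape — 3 training
participants with {6, 3, 3} seizures plus 6 test participants with 1–2
(9 participants, 20 seizures) — at 25 h per recording.  Real cohorts
average ~83 h per participant; 25 h keeps a full end-to-end run on one CPU
in minutes while passing the ≥ 24 h retention filter, and is the package's
declared desk-scale condition.

Two named operating points matter for validation.  The *default* profiles
model realistic amplitudes, under which a tonic-only participant whose
training seizures happen to fall in quiet hours can exhibit elevated false
alarm rates — peri-ictal-only training never shows such a model what
daytime movement looks like, the same failure mode clinical studies report
for tonic phenotypes.  The *positive control*
(`synthetic.positive_control_cohort`, `effect_scale = 2`) doubles every
ictal effect so that all planted structure is unambiguously above
background; under this condition the pipeline is expected to recover every
seizure with FAR24 < 2, and that is what the end-to-end acceptance run
checks.  With `effect_scale = 0` the generator provides the matching
negative control: labels carry no signal and detections must be consistent
with a permutation null.

What the generator does **not** emulate: pediatric physiology, postural
transitions, electrode drying, pre-ictal autonomic changes, seizure
clustering, or realistic streaming-loss statistics (dropouts are explicit
arguments, not a stochastic process).  Consequently, passing end-to-end
controls demonstrates that the pipeline recovers planted structure under
its own assumptions — a positive control of the machinery — and says
nothing about clinical sensitivity or false-alarm rates on patients.

## Numerical choices and degenerate cases

- RQA of a matrix with no off-diagonal recurrences: RR = 0, DET = 0,
  ENTR = 0, L = NaN sentinel.
- Interval conventions: labels mark any 2-s grid interval overlapping the
  closed seizure interval; peri-ictal membership requires positive-measure
  overlap with the padded span (so a 1260-s span covers exactly 630 rows).
  The two differ only at measure-zero boundary touches.
- Spectral-entropy normalization uses the single 10-s boxcar periodogram;
  white noise therefore sits near 0.89 rather than 1.0 (finite-sample
  entropy deficit of an exponential-weight spectrum), and a pure on-bin
  sinusoid at 0.
- Smoothing is idempotent by construction (fill-then-remove); orphan
  removal cannot create a fillable gap shorter than 30 s flanked by labels.
- `grid_search` ties cannot occur: the selection key includes the
  hyperparameters themselves.
- Boosting is seeded; same seed, same data, same result, bit for bit.

## Limitations

The event scorer reports no detection latency (only overlap within the
margin).  The boosting engine is scikit-learn's SAMME AdaBoost; probability
calibration and gradient-boosting variants are out of scope.  The
electrodermal quality screen is a numeric stand-in for a visual judgment.
The heart-rate filter cascade constants are declared defaults, not values
validated against reference beat annotations.  All end-to-end performance
figures in this repository are computed on synthetic cohorts and are not
clinical results.
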