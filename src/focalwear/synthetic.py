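"""Synthetic multimodal cohorts with the statistical structure the
analysis assumes.

No public wearable seizure dataset with expert-labeled focal motor seizures
exists, so every pipeline stage is exercised on generated recordings that
emulate the *feature-relevant* phenomenology of in-hospital wrist
recordings:

- circadian background activity: low-variance accelerometry at night,
  bout-structured aperiodic movement while awake;
- electrodermal background: slow tonic drift plus Poisson spontaneous skin
  conductance responses (more frequent awake than asleep);
- an optical pulse waveform whose rate varies slowly around a resting
  baseline, with broadband artifact coupled to movement intensity (so the
  spectral-entropy quality index degrades exactly when the wrist moves);
- ictal overlays per seizure semiology: tonic seizures add a sustained
  acceleration offset with low-amplitude 8-12 Hz tremor, clonic seizures
  add 2-5 Hz rhythmic bursts; responder seizures add a large delayed
  electrodermal response; ictal tachycardia ramps the heart rate by
  20-50 bpm from onset; a device worn contralateral to the seizure side
  attenuates the ictal movement amplitude;
- optional dropout gaps emulate streaming loss and device swaps.

``effect_scale`` multiplies every ictal effect; 0 produces recordings whose
labels carry no signal at all (negative controls).  All randomness derives
from one seed through independent spawned streams, so recordings are
bit-reproducible.  No claim of physiological fidelity is made beyond the
structure the features respond to.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, lfilter, sosfiltfilt

from .signal_model import (
    MultimodalRecording,
    Segment,
    SeizureAnnotation,
    TimeSeriesChannel,
    write_annotations,
    write_recording,
)

__all__ = [
    "SyntheticProfile",
    "SeizurePlan",
    "SyntheticParticipant",
    "generate_participant",
    "generate_cohort",
    "default_cohort_profiles",
    "positive_control_cohort",
    "POSITIVE_CONTROL_EFFECT_SCALE",
    "write_cohort",
]

ACC_RATE, EDA_RATE, BVP_RATE, TEMP_RATE = 32, 4, 64, 4
#: Epoch chosen so that (with UTC offset 0) recordings start at 08:00 local.
DEFAULT_START_EPOCH = 8 * 3600.0
EDGE_MARGIN_S = 1800.0  # seizures keep this distance from recording edges


@dataclass
class SyntheticProfile:
    """Per-participant phenotype of the generator."""

    participant_id: str
    eda_responder: bool = True
    non_responder_seizures: tuple[int, ...] = ()  # 0-based per-seizure override
    ictal_tachycardia: bool = True
    motor_pattern: str = "clonic"  # tonic | clonic | mixed
    device_on_seizure_side: bool = True
    contralateral_attenuation: float = 0.3
    night_start_local_h: float = 23.0
    night_end_local_h: float = 7.0
    baseline_activity_level: float = 1.0
    acc_noise_g: float = 0.01
    eda_noise_us: float = 0.01
    bvp_noise: float = 2.0
    eda_drift_us: float = 0.3
    scr_rate_awake_per_min: float = 1.0
    scr_rate_asleep_per_min: float = 0.2
    utc_offset_hours: float = 0.0


@dataclass
class SeizurePlan:
    onsets: np.ndarray  # epoch seconds
    durations: np.ndarray  # seconds, within the 10 s - 10 min bounds
    patterns: list[str] = field(default_factory=list)
    responder: list[bool] = field(default_factory=list)


@dataclass
class SyntheticParticipant:
    profile: SyntheticProfile
    recording: MultimodalRecording
    annotations: list[SeizureAnnotation]


def _ou(n: int, dt: float, tau: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Ornstein-Uhlenbeck noise: stationary sd ``sigma``, correlation ``tau``."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    w = rng.normal(size=n) * sigma * np.sqrt(1 - a * a)
    return lfilter([1.0], [1.0, -a], w)


def _is_night_local(t_epoch: np.ndarray, profile: SyntheticProfile) -> np.ndarray:
    tod_h = ((t_epoch + profile.utc_offset_hours * 3600.0) % 86400.0) / 3600.0
    ns, ne = profile.night_start_local_h, profile.night_end_local_h
    return (tod_h >= ns) | (tod_h < ne)


def _plan_seizures(
    profile: SyntheticProfile,
    start: float,
    total_s: float,
    n_seizures: int,
    rng: np.random.Generator,
    duration_range: tuple[float, float],
) -> SeizurePlan:
    """One seizure per equal block of the recording interior: guarantees
    feasibility, non-overlap and wide spacing."""
    if n_seizures == 0:
        return SeizurePlan(np.empty(0), np.empty(0))
    # keep seizures clear of the edges (at least the 10-min feature warm-up),
    # shrinking the margin for short recordings
    margin = min(EDGE_MARGIN_S, max(660.0, total_s / 6.0))
    usable = total_s - 2 * margin
    block = usable / n_seizures
    if block < duration_range[1] + 600.0:
        raise ValueError(
            f"{n_seizures} seizures do not fit in {total_s / 3600:.1f} h"
        )
    durations = rng.uniform(*duration_range, size=n_seizures)
    onsets = np.empty(n_seizures)
    for k in range(n_seizures):
        lo = start + margin + k * block + 0.1 * block
        hi = start + margin + (k + 1) * block - durations[k] - 0.1 * block
        onsets[k] = rng.uniform(lo, hi)
    patterns = []
    for _ in range(n_seizures):
        patterns.append(profile.motor_pattern)
    responder = [
        profile.eda_responder and (k not in profile.non_responder_seizures)
        for k in range(n_seizures)
    ]
    return SeizurePlan(onsets, durations, patterns, responder)


def _ramp_envelope(n: int, rate: float, ramp_s: float = 2.0) -> np.ndarray:
    env = np.ones(n)
    r = min(int(ramp_s * rate), max(1, n // 2))
    env[:r] = np.linspace(0, 1, r)
    env[-r:] = np.linspace(1, 0, r)
    return env


def _make_acc(
    t: np.ndarray,
    profile: SyntheticProfile,
    plan: SeizurePlan,
    effect_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = t.shape[0]
    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0  # gravity on the device z-axis
    acc += rng.normal(scale=profile.acc_noise_g, size=(n, 3))

    # awake movement bouts: aperiodic band-limited noise, Poisson starts
    awake = ~_is_night_local(t, profile)
    awake_hours = awake.sum() / ACC_RATE / 3600.0
    n_bouts = rng.poisson(10.0 * profile.baseline_activity_level * awake_hours)
    awake_idx = np.flatnonzero(awake)
    sos = butter(2, [0.3, 4.0], btype="bandpass", fs=ACC_RATE, output="sos")
    if n_bouts and awake_idx.size:
        starts = rng.choice(awake_idx, size=n_bouts)
        for s0 in np.sort(starts):
            dur = float(np.clip(rng.lognormal(np.log(40.0), 0.5), 5.0, 300.0))
            i1 = min(n, s0 + int(dur * ACC_RATE))
            m = i1 - s0
            if m < ACC_RATE:
                continue
            burst = sosfiltfilt(sos, rng.normal(size=(m, 3)), axis=0)
            acc[s0:i1] += 0.25 * profile.baseline_activity_level * burst * _ramp_envelope(m, ACC_RATE)[:, None]

    # ictal overlays
    atten = 1.0 if profile.device_on_seizure_side else profile.contralateral_attenuation
    for k in range(plan.onsets.shape[0]):
        onset, dur = plan.onsets[k], plan.durations[k]
        i0 = int(np.searchsorted(t, onset))
        i1 = min(n, i0 + int(dur * ACC_RATE))
        m = i1 - i0
        if m <= 0:
            continue
        tt = np.arange(m) / ACC_RATE
        env = _ramp_envelope(m, ACC_RATE)
        pattern = plan.patterns[k]
        halves = [(pattern, slice(0, m))]
        if pattern == "mixed":
            halves = [("tonic", slice(0, m // 2)), ("clonic", slice(m // 2, m))]
        overlay = np.zeros((m, 3))
        for pat, sl in halves:
            mm = sl.stop - sl.start
            if mm <= 0:
                continue
            ts = tt[sl] - tt[sl.start]
            if pat == "tonic":
                f = rng.uniform(8.0, 12.0)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                overlay[sl] += 0.35 * direction[None, :]
                overlay[sl] += 0.08 * np.sin(2 * np.pi * f * ts)[:, None] * direction[None, :]
            else:  # clonic
                f = rng.uniform(2.0, 5.0)
                phases = rng.uniform(0, 2 * np.pi, size=3)
                slow = 0.7 + 0.3 * np.sin(2 * np.pi * ts / max(4.0, mm / ACC_RATE / 3.0))
                overlay[sl] += 0.7 * slow[:, None] * np.sin(
                    2 * np.pi * f * ts[:, None] + phases[None, :]
                )
        acc[i0:i1] += effect_scale * atten * overlay * env[:, None]
    return acc


def _scr_kernel(rate: float, tau_rise: float, tau_decay: float, span_s: float) -> np.ndarray:
    tt = np.arange(int(span_s * rate)) / rate
    k = np.exp(-tt / tau_decay) - np.exp(-tt / tau_rise)
    return k / k.max() if k.max() > 0 else k


def _make_eda(
    t: np.ndarray,
    profile: SyntheticProfile,
    plan: SeizurePlan,
    effect_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = t.shape[0]
    phase = rng.uniform(0, 2 * np.pi)
    eda = 2.0 + profile.eda_drift_us * np.sin(2 * np.pi * t / (6 * 3600.0) + phase)
    eda += _ou(n, 1.0 / EDA_RATE, 600.0, profile.eda_drift_us * 0.3, rng)

    # spontaneous phasic responses
    night = _is_night_local(t, profile)
    rate_per_sample = np.where(
        night, profile.scr_rate_asleep_per_min, profile.scr_rate_awake_per_min
    ) / 60.0 / EDA_RATE
    events = np.flatnonzero(rng.random(n) < rate_per_sample)
    if events.size:
        kern = _scr_kernel(EDA_RATE, 1.0, 10.0, 60.0)
        for i0 in events:
            # heavy-tailed amplitudes: occasional large (startle-sized)
            # responses keep the smoothed-derivative response counter
            # informative in background data
            amp = float(np.clip(rng.lognormal(np.log(0.15), 0.8), 0.02, 1.5))
            i1 = min(n, i0 + kern.shape[0])
            eda[i0:i1] += amp * kern[: i1 - i0]

    # ictal responses for responder seizures
    kern_ict = _scr_kernel(EDA_RATE, 15.0, 90.0, 480.0)
    for k in range(plan.onsets.shape[0]):
        if not plan.responder[k] or effect_scale == 0:
            continue
        amp = rng.uniform(1.0, 2.5) * effect_scale
        delay = rng.uniform(0.0, 20.0)
        i0 = int(np.searchsorted(t, plan.onsets[k] + delay))
        i1 = min(n, i0 + kern_ict.shape[0])
        if i1 > i0:
            eda[i0:i1] += amp * kern_ict[: i1 - i0]
    eda += rng.normal(scale=profile.eda_noise_us, size=n)
    return np.maximum(eda, 0.01)


def _make_bvp(
    t: np.ndarray,
    acc: np.ndarray,
    profile: SyntheticProfile,
    plan: SeizurePlan,
    effect_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = t.shape[0]
    # heart rate trajectory at the BVP rate; the circadian dip eases in and
    # out smoothly (a hard step at bed/wake time is not physiological and
    # would leak spurious HR-difference spikes)
    hr = 70.0 + 6.0 * np.sin(2 * np.pi * t / (4 * 3600.0) + rng.uniform(0, 2 * np.pi))
    hr += _ou(n, 1.0 / BVP_RATE, 300.0, 2.0, rng)
    t1 = t[:: BVP_RATE] if n >= BVP_RATE else t  # 1-Hz support for the smoothing
    night1 = _is_night_local(t1, profile).astype(float)
    night_smooth = uniform_filter1d(night1, size=1200, mode="nearest")
    hr -= 8.0 * np.interp(t, t1, night_smooth)
    hr = np.clip(hr, 50.0, 90.0)
    if profile.ictal_tachycardia and effect_scale > 0:
        for k_s in range(plan.onsets.shape[0]):
            onset, dur = plan.onsets[k_s], plan.durations[k_s]
            delta = rng.uniform(25.0, 45.0) * effect_scale
            rel = t - onset
            ramp = np.clip(rel / 10.0, 0.0, 1.0)  # 10-s rise
            decay = np.exp(-np.clip(rel - dur, 0.0, None) / 60.0)
            hr += delta * ramp * np.where(rel >= 0, decay, 0.0)
    hr = np.clip(hr, 40.0, 170.0)

    phase = 2 * np.pi * np.cumsum(hr / 60.0) / BVP_RATE
    pulse = 40.0 * (-np.cos(phase) + 0.25 * np.sin(2 * phase + 0.8))

    # movement-coupled broadband artifact (the SQI driver)
    dev = np.linalg.norm(acc - np.array([0.0, 0.0, 1.0])[None, :], axis=1)
    dev64 = np.repeat(dev, BVP_RATE // ACC_RATE)[:n]
    artifact = rng.normal(size=n) * (100.0 * np.clip(dev64 - 0.03, 0.0, None))
    return pulse + artifact + rng.normal(scale=profile.bvp_noise, size=n)


def generate_participant(
    profile: SyntheticProfile,
    total_hours: float = 25.0,
    n_seizures: int = 3,
    seed: int = 0,
    effect_scale: float = 1.0,
    start_time: float = DEFAULT_START_EPOCH,
    duration_range_s: tuple[float, float] = (20.0, 120.0),
    dropouts: list[tuple[float, float]] | None = None,
) -> tuple[MultimodalRecording, list[SeizureAnnotation]]:
    """Generate one participant's multimodal recording plus annotations.

    ``dropouts`` is a list of ``(offset_s, duration_s)`` streaming-loss gaps
    relative to the recording start; gaps must not cover planted seizures.
    Same seed, same arguments -> bit-identical output.
    """
    if total_hours <= 0:
        raise ValueError("total_hours must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF0CA]))
    total_s = float(int(total_hours * 3600))
    plan = _plan_seizures(profile, start_time, total_s, n_seizures, rng, duration_range_s)

    t_acc = start_time + np.arange(int(total_s * ACC_RATE)) / ACC_RATE
    t_eda = start_time + np.arange(int(total_s * EDA_RATE)) / EDA_RATE
    t_bvp = start_time + np.arange(int(total_s * BVP_RATE)) / BVP_RATE

    acc = _make_acc(t_acc, profile, plan, effect_scale, rng)
    eda = _make_eda(t_eda, profile, plan, effect_scale, rng)
    bvp = _make_bvp(t_bvp, acc, profile, plan, effect_scale, rng)
    temp = 33.0 + 0.5 * np.sin(2 * np.pi * t_eda / 86400.0) + rng.normal(scale=0.02, size=t_eda.shape[0])

    # cut into segments around dropout gaps (cut points on whole seconds)
    gaps = sorted(dropouts or [])
    for off, dur in gaps:
        for k in range(plan.onsets.shape[0]):
            s0 = plan.onsets[k] - start_time
            s1 = s0 + plan.durations[k]
            if off < s1 and off + dur > s0:
                raise ValueError("dropout gap covers a planted seizure")
    bounds, cursor = [], 0.0
    for off, dur in gaps:
        off, dur = float(int(off)), float(int(dur))
        if off > cursor:
            bounds.append((cursor, off))
        cursor = off + dur
    if cursor < total_s:
        bounds.append((cursor, total_s))

    segments = []
    for a, b in bounds:
        seg = Segment(start_time=start_time + a)
        for name, arr, rate in (
            ("ACC", acc, ACC_RATE),
            ("EDA", eda, EDA_RATE),
            ("BVP", bvp, BVP_RATE),
            ("TEMP", temp, TEMP_RATE),
        ):
            i0, i1 = int(a * rate), int(b * rate)
            seg.channels[name] = TimeSeriesChannel(
                name=name, start_time=start_time + a, sample_rate=float(rate),
                samples=arr[i0:i1],
            )
        segments.append(seg)

    recording = MultimodalRecording(
        participant_id=profile.participant_id,
        segments=segments,
        device_wrist="left",
        utc_offset_hours=profile.utc_offset_hours,
    )
    annotations = []
    for k in range(plan.onsets.shape[0]):
        onset, dur = float(plan.onsets[k]), float(plan.durations[k])
        pattern = plan.patterns[k]
        flags = {"mixed": frozenset({"tonic", "clonic"})}.get(pattern, frozenset({pattern}))
        night = bool(_is_night_local(np.array([onset]), profile)[0])
        annotations.append(
            SeizureAnnotation(
                seizure_id=f"{profile.participant_id}-{k + 1}",
                onset=onset,
                offset=onset + dur,
                motor_flags=flags,
                tachycardia=profile.ictal_tachycardia,
                vigilance="asleep" if night else "awake",
                seizure_side_matches_device=profile.device_on_seizure_side,
            )
        )
    return recording, annotations


def default_cohort_profiles() -> tuple[list[tuple[SyntheticProfile, int]], list[tuple[SyntheticProfile, int]]]:
    """The default cohort shape: 3 training participants with {6, 3, 3}
    seizures and 6 test participants with 1-2 each (20 seizures, 9
    participants in total)."""
    train = [
        (SyntheticProfile("S01", motor_pattern="clonic"), 6),
        (SyntheticProfile("S02", motor_pattern="tonic"), 3),
        (SyntheticProfile("S03", motor_pattern="mixed", device_on_seizure_side=False), 3),
    ]
    test_specs = [
        ("T01", "clonic", True, 2),
        ("T02", "tonic", True, 1),
        ("T03", "mixed", False, 1),
        ("T04", "clonic", True, 2),
        ("T05", "tonic", True, 1),
        ("T06", "clonic", True, 1),
    ]
    test = [
        (SyntheticProfile(pid, motor_pattern=pat, device_on_seizure_side=side), n)
        for pid, pat, side, n in test_specs
    ]
    return train, test


def generate_cohort(
    profiles: list[tuple[SyntheticProfile, int]] | None = None,
    total_hours: float = 25.0,
    seed: int = 0,
    effect_scale: float = 1.0,
) -> list[SyntheticParticipant]:
    """Generate a cohort; with ``profiles=None`` the default 9-participant,
    20-seizure preset (train then test participants).

    Per-participant sub-seeds derive deterministically from the master seed.
    """
    if profiles is None:
        train, test = default_cohort_profiles()
        profiles = train + test
    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(profiles))]
    cohort = []
    for (profile, n_seiz), sub in zip(profiles, sub_seeds):
        rec, ann = generate_participant(
            profile, total_hours=total_hours, n_seizures=n_seiz, seed=sub,
            effect_scale=effect_scale,
        )
        cohort.append(SyntheticParticipant(profile, rec, ann))
    return cohort


#: Ictal effect multiplier of the strong-effect positive-control condition:
#: effects unambiguously above background (doubled movement, electrodermal
#: and tachycardia amplitudes), under which the full pipeline is expected to
#: recover every planted seizure.  Default profiles model realistic
#: amplitudes instead.
POSITIVE_CONTROL_EFFECT_SCALE = 2.0


def positive_control_cohort(seed: int, total_hours: float = 25.0) -> list[SyntheticParticipant]:
    """The default cohort under the strong-effect positive-control condition."""
    return generate_cohort(
        total_hours=total_hours, seed=seed, effect_scale=POSITIVE_CONTROL_EFFECT_SCALE
    )


def write_cohort(root: str | Path, cohort: list[SyntheticParticipant], seed: int | None = None) -> None:
    """Write the session-directory + annotation CSV formats that the reader
    understands, plus a manifest of the planted truth."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "participants": []}
    for sp in cohort:
        pid = sp.profile.participant_id
        write_recording(root / pid, sp.recording)
        write_annotations(root / pid / "annotations.csv", sp.annotations)
        manifest["participants"].append(
            {
                "participant_id": pid,
                "profile": asdict(sp.profile),
                "n_seizures": len(sp.annotations),
                "seizures": [
                    {"seizure_id": a.seizure_id, "onset": a.onset, "offset": a.offset}
                    for a in sp.annotations
                ],
            }
        )
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
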