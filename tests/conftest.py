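"""Shared fixtures: small synthetic recordings reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from focalwear.dataset import prepare_participant
from focalwear.synthetic import SyntheticProfile, generate_participant


@pytest.fixture(scope="session")
def small_participant():
    """One 4-h recording with 3 strong seizures: enough for harness tests."""
    profile = SyntheticProfile("SMALL1")
    recording, annotations = generate_participant(
        profile, total_hours=4.0, n_seizures=3, seed=11
    )
    return prepare_participant(recording, annotations)


@pytest.fixture(scope="session")
def quiet_profile():
    """Noise-free, drift-free profile for closed-form feature checks."""
    return SyntheticProfile(
        "QUIET1",
        acc_noise_g=0.0,
        eda_noise_us=0.0,
        bvp_noise=0.0,
        eda_drift_us=0.0,
        scr_rate_awake_per_min=0.0,
        scr_rate_asleep_per_min=0.0,
        baseline_activity_level=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
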