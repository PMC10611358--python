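import numpy as np
import pytest

from eegmrcnn.data import BANDS, Recording
from eegmrcnn.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10+10 subjects, 24 s each, beta power ratio 1.8 — quick but realistic."""
    spec = CohortSpec(
        n_group_a=10, n_group_b=10, duration_s=24.0,
        band_effects=((BANDS["beta"], 1.8),), seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def artifact_recording():
    """One 60 s subject with frequent ocular transients."""
    spec = CohortSpec(n_group_a=1, n_group_b=1, duration_s=60.0,
                      artifact_rate=10.0, seed=5)
    return generate_cohort(spec)[0]


@pytest.fixture(scope="session")
def clean_recording():
    """One 60 s artifact-free subject."""
    spec = CohortSpec(n_group_a=1, n_group_b=1, duration_s=60.0,
                      artifact_rate=0.0, seed=6)
    return generate_cohort(spec)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(rng, n_channels=6, duration_s=20.0, rate_hz=250.0,
                   subject_id="s0", group="DD"):
    labels = ("Fp1", "Fp2", "F3", "F4", "F7", "F8")[:n_channels]
    x = rng.standard_normal((n_channels, int(duration_s * rate_hz)))
    return Recording(x, rate_hz, labels, subject_id, group)
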