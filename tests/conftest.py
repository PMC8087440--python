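import numpy as np
import pytest

from noxsense import gen_recording, gen_template


@pytest.fixture
def rng():
    return np.random.default_rng(20210413)


@pytest.fixture(scope="session")
def template():
    return gen_template()


@pytest.fixture
def clean_recording(template):
    """Noise-free recording for one subject: exact embedding, zero jitter."""
    row = {"subject_id": "s0000", "x": 1.0, "y": 1.87}
    return gen_recording(row, template, n_trials=5, n_clinical=1,
                         jitter_sd_ms=0.0, trial_noise_sd=0.0,
                         background=("white", 0.0), seed=0)


@pytest.fixture
def noisy_recording(template):
    row = {"subject_id": "s0001", "x": 0.9, "y": 1.5}
    return gen_recording(row, template, n_trials=10, n_clinical=2,
                         seed=42)
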