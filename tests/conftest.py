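import numpy as np
import pytest

from eddx.cohort import CohortConfig, generate_cohort, generate_followup


@pytest.fixture(scope="session")
def small_cohort():
    """Mid-size noisy cohort shared across tests (600 patients, fixed seed)."""
    cfg = CohortConfig(n_patients=600, noise=0.05, seed=42)
    records, truths = generate_cohort(cfg)
    return cfg, records, truths


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: engine labels must equal latent labels exactly."""
    cfg = CohortConfig(n_patients=800, noise=0.0, seed=7)
    records, truths = generate_cohort(cfg)
    followups = generate_followup(records, truths, cfg)
    return cfg, records, truths, followups


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
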