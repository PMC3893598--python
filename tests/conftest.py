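import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nirsload as nl

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_session():
    """One simulated session under default conditions, fully preprocessed."""
    ds = nl.simulate_dataset(11)
    clean = nl.preprocess_pipeline(ds.recording)
    trials = nl.segment_trials(clean, ds.timeline)
    return ds, clean, trials


@pytest.fixture(scope="session")
def noise_free_session():
    """Noise- and artifact-free session: pure hemodynamics on active channels."""
    cfg = nl.noise_free_config(5)
    ds = nl.simulate_dataset(5, config=cfg)
    clean = nl.preprocess_pipeline(ds.recording)
    trials = nl.segment_trials(clean, ds.timeline)
    return ds, clean, trials, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
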