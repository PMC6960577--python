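import numpy as np
import pytest

from affectflight.evaluate import PipelineConfig
from affectflight.preprocess import PreprocConfig, preprocess_session, windowize
from affectflight.synth import SynthConfig, generate_cohort, generate_session


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A reduced cohort: 3 flights of 100 s, EEG at 200 Hz."""
    return SynthConfig(
        n_flights=3, session_duration=100.0, fs_eeg=200.0, rng_seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_session(small_cfg, "RC1", seed=123)


@pytest.fixture(scope="session")
def windowed_samples(small_session):
    cfg = PreprocConfig()
    return windowize(preprocess_session(small_session, cfg), cfg)


@pytest.fixture(scope="session")
def fast_pipeline() -> PipelineConfig:
    return PipelineConfig(epochs=60, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
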