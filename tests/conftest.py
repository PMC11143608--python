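import numpy as np
import pytest

from eegtcn.preprocessing import PreprocessConfig, preprocess_recording
from eegtcn.synthetic import SimulationConfig, simulate_cohort
from eegtcn.types import SegmentSet


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim_config():
    # 4 channels / 10 s keeps simulation cheap while exercising the full path
    return SimulationConfig(
        n_channels=4, rate=500.0, duration=10.0, event_rate=18.0,
        event_duration=(0.8, 1.5), seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    return simulate_cohort(3, 3, small_sim_config)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    segments = SegmentSet()
    for rec in small_cohort:
        segments.extend(preprocess_recording(rec, PreprocessConfig()))
    return segments
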