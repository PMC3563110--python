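import numpy as np
import pytest

from fcmotion.config import AnalysisConfig
from fcmotion.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small motion-contaminated cohort shared across tests."""
    return generate_cohort(SyntheticConfig(n_per_group=8, n_rois=40,
                                           n_frames=120, seed=3))


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort without motion spikes or planted effects (null signal)."""
    return generate_cohort(SyntheticConfig(
        n_per_group=8, n_rois=40, n_frames=120, seed=4,
        spike_rate_mean=0.0, age_slope=0.0,
        delta_combined=0.0, delta_inattentive=0.0, delta_sensorimotor=0.0,
    ))


@pytest.fixture(scope="session")
def medium_cohort():
    """Large enough for edge-wise FDR discoveries at the planted effect
    sizes."""
    return generate_cohort(SyntheticConfig(n_per_group=30, n_rois=40,
                                           n_frames=200, seed=5,
                                           short_range_max_mm=60.0))


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
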