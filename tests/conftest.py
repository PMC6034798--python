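import numpy as np
import pytest

from acg.cohort import CohortConfig, cohort_feature_table, generate_cohort
from acg.signal_model import make_pulse_spec

# desk-scale record geometry used throughout the suite: 3.2 ms records at
# 10 MHz with 1 ms analysis windows after a 0.2 ms onset settle margin
SHORT_FS = 10e6
SHORT_DURATION = 3.2e-3
SHORT_WINDOW = 1.0e-3
SHORT_SETTLE = 2.0e-4


@pytest.fixture(scope="session")
def short_spec():
    return make_pulse_spec(sampling_rate_hz=SHORT_FS, record_duration_s=SHORT_DURATION)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size (97-subject) synthetic cohort at desk-scale record geometry."""
    return generate_cohort(CohortConfig.short_records(seed=2024))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return cohort_feature_table(default_cohort)
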