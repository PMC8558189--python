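import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `reference` importable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Separable 12-subject cohort at reduced scale, shared across tests."""
    from elbnd import CohortSpec, generate_cohort

    spec = CohortSpec(n_negative=6, n_positive=6, n_channels=3,
                      duration_s=60.0, seed=7)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from elbnd import extract_features, preprocess_record

    _, records = small_cohort
    return [extract_features(preprocess_record(r)) for r in records]
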