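import numpy as np
import pytest
from hypothesis import settings

import tvdtsim as tv

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def canonical_fit():
    """Gamma clinical fit from the published moments (mean 297 d, SD 169 d)."""
    return tv.fit_from_moments(297.0, 169.0)


@pytest.fixture(scope="session")
def cohort30(canonical_fit):
    """A deterministic 30-patient virtual cohort."""
    return tv.generate_cohort(tv.CohortConfig(n=30, seed=42, tvdt_source=canonical_fit))


@pytest.fixture(scope="session")
def noisy_records(cohort30):
    """Three measurement sessions at the default observer noise."""
    return tv.measure_cohort(cohort30, tv.ObserverNoise(sd=0.5), n_sessions=3, seed=7)


@pytest.fixture(scope="session")
def noisy_estimates(noisy_records, cohort30):
    return tv.estimate_cohort_tvdt(noisy_records, cohort30)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
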