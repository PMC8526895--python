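import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic synthetic cohort shared across tests."""
    from habitatrad import synthetic as syn

    spec = syn.CohortSpec(
        n_per_class={"NSCLC": 6, "BID": 6}, radius_range_mm=(6.0, 8.0), seed=42
    )
    vois, truths, records = syn.generate_cohort_in_memory(spec)
    return spec, vois, truths, records


@pytest.fixture(scope="session")
def one_voi(small_cohort):
    return small_cohort[1][0]
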