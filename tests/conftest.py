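import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def item_banks():
    from harmonex.synthetic import default_item_banks

    source, target, rho = default_item_banks()
    return source, target, rho


@pytest.fixture(scope="session")
def small_dataset():
    """Small paired dataset for fast mapper/evaluation tests."""
    from harmonex.synthetic import make_cohort_dataset

    return make_cohort_dataset(n=300, scenario="unidimensional", seed=123)


@pytest.fixture(scope="session")
def cohort_scale_dataset():
    """One cohort-scale dataset in the partial-overlap scenario."""
    from harmonex.synthetic import make_cohort_dataset

    return make_cohort_dataset(n=1551, scenario="correlated_traits", seed=7)
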