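import numpy as np
import pytest

from plrwave import CohortSpec, build_feature_rows, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-scale cohort (6 healthy + 6 patients) at generator defaults."""
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def default_rows(default_cohort):
    return build_feature_rows(default_cohort, w=1.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
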