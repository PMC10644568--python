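import numpy as np
import pytest

from etmpheno import generate_cohort, load_cohort_fixture
from etmpheno.simulate import NoiseConfig, default_group_configs


@pytest.fixture(scope="session")
def fixture_cohort():
    """The bundled per-subject study cohort (28 records)."""
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic cohort (3 per group) with default noise."""
    return generate_cohort(n_per_group={"AN": 3, "FA": 3, "CA": 3}, seed=11)


@pytest.fixture(scope="session")
def noiseless_configs():
    return default_group_configs(noise=NoiseConfig.zero())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
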