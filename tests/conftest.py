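import numpy as np
import pytest

from tojreplay.synthetic import (
    DesignSpec,
    GeneratorParams,
    generate_cohort,
    generate_dataset,
)
from tojreplay.trial_data import filter_rt

#: small design for tests that only need mechanics, not statistical power
SMALL_SPEC = DesignSpec(n_sessions=10, trials_per_session=50, exposures=5)


@pytest.fixture(scope="session")
def default_table():
    """One full-size (5000-trial) strict-forward synthetic subject."""
    return generate_dataset(seed=101)


@pytest.fixture(scope="session")
def filtered_table(default_table):
    return filter_rt(default_table)


@pytest.fixture(scope="session")
def small_table():
    """500-trial subject for fast mechanical tests."""
    return generate_dataset(SMALL_SPEC, seed=202)


@pytest.fixture(scope="session")
def strict_cohort():
    """Six strict-forward subjects at the full design size, RT-filtered."""
    return filter_rt(generate_cohort(6, seed=303))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
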