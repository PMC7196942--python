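import numpy as np
import pytest

from casus.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: n=750, seed 0, study-condition defaults."""
    return generate_cohort(GeneratorConfig())


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort for law-of-large-numbers checks."""
    return generate_cohort(GeneratorConfig(n_patients=20000, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
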