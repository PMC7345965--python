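import numpy as np
import pytest

from aastone import DCVConfig, default_cohort_spec, double_cross_validate, generate_cohort


@pytest.fixture(scope="session")
def default_table():
    """The default synthetic study cohort: 12 CNT + 15 SF, 35 analytes."""
    return generate_cohort(default_cohort_spec(seed=42))


@pytest.fixture(scope="session")
def default_dcv_result(default_table):
    """One repeated-DCV run on the default cohort, shared across tests."""
    return double_cross_validate(default_table, DCVConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
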