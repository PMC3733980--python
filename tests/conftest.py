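import pytest
from hypothesis import settings

# property tests must be reproducible run to run
settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from msilac.datasets import (
    load_annexin_a1,
    load_dose_table,
    load_time_table,
    load_turnover_table,
)


@pytest.fixture(scope="session")
def annexin_a1():
    return load_annexin_a1()


@pytest.fixture(scope="session")
def dose_table():
    return load_dose_table()


@pytest.fixture(scope="session")
def time_table():
    return load_time_table()


@pytest.fixture(scope="session")
def turnover_table():
    return load_turnover_table()
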