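import pytest
from hypothesis import HealthCheck, settings

from phagekit.codontab import CodonTable
from phagekit.diversity import default_cdr2_design, default_cdr3_design
from phagekit.example import engineer_scaffold

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ecoli_table():
    return CodonTable.ecoli()


@pytest.fixture(scope="session")
def cdr2_design():
    return default_cdr2_design()


@pytest.fixture(scope="session")
def cdr3_design():
    return default_cdr3_design()


@pytest.fixture(scope="session")
def engineered():
    return engineer_scaffold()
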