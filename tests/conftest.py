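import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2_cases():
    from mplcdx import load_table2

    return load_table2()


@pytest.fixture(scope="session")
def table3():
    from mplcdx import load_table3

    return load_table3()
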