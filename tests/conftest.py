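import pytest

from stroke_cea import ParameterSet, default_life_table, evaluate


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def base_eval(params, life_table):
    """Base-case two-arm evaluation, shared across tests (read-only)."""
    return evaluate(params, life_table)
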