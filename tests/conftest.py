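import pytest

from lfqdiff import RunConfig, fixture_toy_table, make_builtin_designs, run_differential


@pytest.fixture(scope="session")
def designs():
    return make_builtin_designs()


@pytest.fixture(scope="session")
def toy():
    """The deterministic hand-constructed pan-UB toy experiment."""
    return fixture_toy_table()


@pytest.fixture(scope="session")
def toy_results(toy):
    """Differential results of the toy experiment (computed once)."""
    table, _ = toy
    return run_differential(table, RunConfig())
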