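import pytest

from grainphi import (example1_universe, example2_universe, fig2_universe)


@pytest.fixture(scope="session")
def ex1():
    return example1_universe()


@pytest.fixture(scope="session")
def ex2():
    return example2_universe()


@pytest.fixture(scope="session")
def fig2a():
    return fig2_universe(0.0)


@pytest.fixture(scope="session")
def fig2b():
    return fig2_universe(0.01)
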