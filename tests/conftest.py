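import pytest

from eccqspr import MolecularGraph
from eccqspr.dataset import chlorpromazine_fixture


def path_graph(n: int) -> MolecularGraph:
    return MolecularGraph([(i, i + 1) for i in range(1, n)])


def cycle_graph(n: int) -> MolecularGraph:
    return MolecularGraph([(i, i + 1) for i in range(1, n)] + [(n, 1)])


@pytest.fixture(scope="session")
def k2():
    return path_graph(2)


@pytest.fixture(scope="session")
def p3():
    return path_graph(3)


@pytest.fixture(scope="session")
def c6():
    return cycle_graph(6)


@pytest.fixture(scope="session")
def chlorpromazine():
    """The chlorpromazine heavy-atom graph with its printed reference data."""
    return chlorpromazine_fixture()
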