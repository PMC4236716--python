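import hypothesis
import networkx as nx
import pytest

from spanet.synthetic import GeneratorParams, make_benchmark

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def benchmark():
    """Default 500-protein benchmark with planted ground truth."""
    return make_benchmark(GeneratorParams(seed=0))


@pytest.fixture(scope="session")
def small_benchmark():
    """Fast 200-protein benchmark for pipeline-level tests."""
    return make_benchmark(GeneratorParams(n_proteins=200, seed=3))


@pytest.fixture()
def bridged_cliques():
    """Two 6-cliques joined by a single bridge edge."""
    g = nx.Graph()
    a = [f"A{i}" for i in range(6)]
    b = [f"B{i}" for i in range(6)]
    for grp in (a, b):
        for i in range(6):
            for j in range(i + 1, 6):
                g.add_edge(grp[i], grp[j])
    g.add_edge("A0", "B0")
    return g
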