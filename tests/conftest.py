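import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from phononet import build_network
from phononet.synth import SynthConfig, generate, generate_benchmark_suite, tiny_lexicon


@pytest.fixture(scope="session")
def tiny_lex():
    return tiny_lexicon()


@pytest.fixture(scope="session")
def tiny_net(tiny_lex):
    return build_network(tiny_lex)


@pytest.fixture(scope="session")
def benchmark_suite():
    return generate_benchmark_suite(seed=0)


@pytest.fixture(scope="session")
def small_net(benchmark_suite):
    return build_network(benchmark_suite["small"]["lexicon"])


@pytest.fixture(scope="session")
def medium_net(benchmark_suite):
    return build_network(benchmark_suite["medium"]["lexicon"])


@pytest.fixture(scope="session")
def toy8():
    """Triangle + one edge + 3 isolates: giant 3, one 2-node island, 3 hermits."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e")])
    g.add_nodes_from(["x", "y", "z"])
    return g


def synth_lexicon(n_lemmas: int, seed: int, **kwargs):
    return generate(SynthConfig(n_lemmas=n_lemmas, seed=seed, **kwargs))
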