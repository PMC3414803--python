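import numpy as np
import pytest

from tbssr.mcl import inflation_sweep
from tbssr.similarity import all_vs_all, build_graph
from tbssr.synthetic import (
    SynthParams,
    default_element_suite,
    generate_annotated_replicon,
    generate_protein_set,
)


@pytest.fixture(scope="session")
def default_corpus():
    """The standard synthetic corpus: 8 families + 20 singletons, seed 1."""
    proteins, truth = generate_protein_set(SynthParams(seed=1))
    return proteins, truth


@pytest.fixture(scope="session")
def default_graph(default_corpus):
    proteins, _truth = default_corpus
    hits = all_vs_all(proteins)
    graph = build_graph(
        hits,
        node_ids=[p.id for p in proteins],
        database_size=sum(p.length for p in proteins),
    )
    return hits, graph


@pytest.fixture(scope="session")
def default_sweep(default_graph):
    _hits, graph = default_graph
    return inflation_sweep(graph)


@pytest.fixture(scope="session")
def element_suite():
    return generate_annotated_replicon(default_element_suite())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_protein(rng, length):
    from tbssr.records import AA_ALPHABET

    return "".join(AA_ALPHABET[k] for k in rng.integers(0, 20, size=length))
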