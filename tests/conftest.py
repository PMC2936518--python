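import numpy as np
import pytest

from synlet.go_semantics import AnnotationSet, Ontology
from synlet.synthetic import FixtureConfig, fixture_feature_matrix, generate_fixture


@pytest.fixture(scope="session")
def planted_bundle():
    """Default study conditions: 300 genes, 2000 pairs, 7.1% SL, signal 0.8."""
    return generate_fixture(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def planted_matrix(planted_bundle):
    return fixture_feature_matrix(planted_bundle)


@pytest.fixture()
def chain_ontology():
    """root <- c1 <- c2 plus a sibling s of c1, all biological_process."""
    parents = {
        "GO:0000001": set(),
        "GO:0000002": {"GO:0000001"},
        "GO:0000003": {"GO:0000002"},
        "GO:0000004": {"GO:0000001"},
    }
    ns = {t: "biological_process" for t in parents}
    return Ontology(parents, ns)


def random_network(rng: np.random.Generator, n_nodes: int, n_edges: int, name="r"):
    from synlet.networks import WeightedNetwork

    genes = [f"N{i:03d}" for i in range(n_nodes)]
    net = WeightedNetwork(name=name)
    for _ in range(n_edges):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        w = float(rng.uniform(-1, 1))
        net.add_edge(genes[i], genes[j], w)
    return genes, net
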