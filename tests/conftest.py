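import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from phyloconflict.examples import (  # noqa: E402
    mesangiosperm_scheme,
    mesangiosperm_tree,
)


@pytest.fixture(scope="session")
def scheme():
    return mesangiosperm_scheme()


@pytest.fixture(scope="session")
def species_network():
    return mesangiosperm_tree()


@pytest.fixture(scope="session")
def species_tree(species_network):
    return species_network.to_gene_tree()


def random_tree_newick(rng: np.random.Generator, labels) -> str:
    """Random rooted binary tree with random branch lengths (test helper)."""
    nodes = [f"{l}:{rng.uniform(0.1, 2):.3f}" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (f"({nodes[i]},{nodes[j]})"
                  f":{rng.uniform(0.1, 2):.3f}")
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0].rsplit(":", 1)[0] + ";"
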