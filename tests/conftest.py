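import logging

import numpy as np
import pytest

from netenrich.model import GeneSet, GeneSetCollection, Network
from netenrich.synthetic import make_random_gene_sets, make_scalefree_network

logging.getLogger("netenrich").setLevel(logging.ERROR)


@pytest.fixture
def toy_net() -> Network:
    """The 4-node hand example: triangle A-B-C plus pendant D on C."""
    return Network([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")], name="toy")


@pytest.fixture
def toy_ags() -> GeneSet:
    return GeneSet("AGS1", frozenset({"A", "B"}))


@pytest.fixture
def toy_fgs() -> GeneSet:
    return GeneSet("FGS1", frozenset({"C", "D"}))


@pytest.fixture(scope="session")
def small_ba_net() -> Network:
    """500-node preferential-attachment network shared across tests."""
    return make_scalefree_network(500, 3, seed=11)


@pytest.fixture(scope="session")
def big_ba_net() -> Network:
    """2000-node preferential-attachment network (convergence-scale runs)."""
    return make_scalefree_network(2000, 5, seed=1)


@pytest.fixture(scope="session")
def calib_net() -> Network:
    """5000-node network for null-calibration checks.

    Sets of 20-200 genes stay below ~4% of the nodes here, inside the
    operating regime of the parametric null (see docs/methods.md); on much
    smaller networks the expected-edge formula is biased for large sets.
    """
    return make_scalefree_network(5000, 10, seed=1)


def random_simple_graph(rng: np.random.Generator, n_nodes: int, p: float) -> Network:
    """Erdos-Renyi helper for oracle-equivalence tests."""
    names = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    ]
    return Network(edges)


def brute_force_between_edges(net: Network, a: frozenset, f: frozenset) -> int:
    """Independent edge-count oracle: literal double loop with exclusions."""
    count = 0
    for u, v in net.edges:
        if u in a and v in a:
            continue
        if u in f and v in f:
            continue
        if (u in a and v in f) or (v in a and u in f):
            count += 1
    return count
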