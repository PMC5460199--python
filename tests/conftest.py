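import numpy as np
import pytest
import scipy.sparse as sp

from mcgfinder import EdgeList, GeneNetwork, MutationMatrix, PlantedScenario, generate


@pytest.fixture
def path_network():
    """2-gene path graph: A = [[0,1],[1,0]], L = [[1,-1],[-1,1]]."""
    return GeneNetwork.from_edges(EdgeList.from_pairs([("G1", "G2")]), ["G1", "G2"])


@pytest.fixture
def empty_network():
    def make(p):
        genes = [f"G{j}" for j in range(p)]
        return GeneNetwork.from_edges(EdgeList(), genes)

    return make


@pytest.fixture
def two_block_fixture():
    """Asymmetric noise-free two-block instance with exact planted structure.

    Block 1: samples 0-4 mutate genes 0-3; block 2: samples 5-7 mutate
    genes 4-5. Rank-one extraction must peel block 1 first, then block 2.
    """
    scenario = PlantedScenario(
        n=8,
        p=6,
        components=(
            (tuple(range(5)), tuple(range(4)), 1.0),
            (tuple(range(5, 8)), (4, 5), 1.0),
        ),
        background_rate=0.0,
        module_edge_prob=0.0,
        background_edge_prob=0.0,
        seed=0,
    )
    return generate(scenario)


def random_planted_small(seed: int) -> PlantedScenario:
    """Small planted instance preserving the default study's per-sample signal."""
    return PlantedScenario(
        n=8,
        p=8,
        components=((tuple(range(4)), tuple(range(4)), 0.75),),
        background_rate=0.02,
        module_edge_prob=0.5,
        background_edge_prob=0.05,
        seed=seed,
    )


def random_matrix_network(rng: np.random.Generator, n: int, p: int, density: float = 0.15):
    """Random binary matrix plus a random normalized network over p genes."""
    X = (rng.random((n, p)) < density).astype(float)
    genes = [f"G{j}" for j in range(p)]
    pairs = []
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < 0.2:
                pairs.append((genes[i], genes[j]))
    net = GeneNetwork.from_edges(EdgeList.from_pairs(pairs), genes)
    return X, net
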