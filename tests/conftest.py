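import numpy as np
import pandas as pd
import pytest

from pindiff import EdgeList, ExpressionMatrix, SampleNetwork, WeightedNetwork


def make_network(records) -> WeightedNetwork:
    return WeightedNetwork.from_edge_list(EdgeList.from_records(records))


def as_sample(network: WeightedNetwork, sample_id: str = "s") -> SampleNetwork:
    """Whole network viewed as a single sample (all genes expressed)."""
    return SampleNetwork(sample_id, network, list(network.nodes), network.adjacency)


def cycle_network(n: int, weight: float = 1.0) -> WeightedNetwork:
    return make_network(
        [(f"g{i:03d}", f"g{(i + 1) % n:03d}", weight) for i in range(n)]
    )


def circulant_network(n: int, offsets) -> WeightedNetwork:
    recs = []
    for i in range(n):
        for off in offsets:
            recs.append((f"g{i:03d}", f"g{(i + off) % n:03d}", 1.0))
    return make_network(recs)


@pytest.fixture
def path_abc() -> WeightedNetwork:
    """Path graph A - B - C with unit weights."""
    return make_network([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def star_k13() -> WeightedNetwork:
    """Star with hub H and three unit-weight leaves."""
    return make_network([("H", "L1", 1.0), ("H", "L2", 1.0), ("H", "L3", 1.0)])


@pytest.fixture
def two_node() -> SampleNetwork:
    return as_sample(make_network([("A", "B", 1.0)]))


def random_weighted_network(n: int, p: float, rng: np.random.Generator) -> WeightedNetwork:
    """Connected-ish Erdős–Rényi graph with uniform weights for oracle tests."""
    recs = []
    for i in range(n - 1):  # spanning path keeps it connected
        recs.append((f"n{i:02d}", f"n{i + 1:02d}", float(rng.uniform(0.2, 1.0))))
    for i in range(n):
        for j in range(i + 2, n):
            if rng.random() < p:
                recs.append((f"n{i:02d}", f"n{j:02d}", float(rng.uniform(0.2, 1.0))))
    return make_network(recs)


def expression_from_frame(values: pd.DataFrame, condition: dict, platform="rnaseq"):
    return ExpressionMatrix(values, pd.Series(condition), platform=platform)
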