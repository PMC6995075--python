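import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from skincorrect import FeatureTable, SimulationConfig, simulate


def make_toy_tree() -> TreeNode:
    tree = TreeNode.read(["((A:1,B:2):1,C:3):0;"])
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree


@pytest.fixture
def toy_tree() -> TreeNode:
    return make_toy_tree()


@pytest.fixture
def toy_table() -> FeatureTable:
    counts = pd.DataFrame(
        [[5, 0, 2], [3, 1, 0], [0, 0, 7]],
        index=["s1", "s2", "s3"], columns=["A", "B", "C"])
    return FeatureTable(counts)


@pytest.fixture(scope="session")
def sim_default():
    """One default simulated dataset shared across tests (seed fixed)."""
    return simulate(SimulationConfig(seed=7))


def swab_present_features(sim) -> set:
    swabs = sim.metadata.index[sim.metadata["sample_type"] == "swab"]
    present = (sim.table.counts.loc[swabs] > 0).any()
    return set(sim.table.counts.columns[present])


def random_distance_matrix(n: int, rng) -> pd.DataFrame:
    """Euclidean distances of random points (guaranteed metric)."""
    from scipy.spatial.distance import pdist, squareform

    points = rng.standard_normal((n, 4))
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(squareform(pdist(points)), index=ids, columns=ids)
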