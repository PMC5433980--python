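import random

import numpy as np
import pytest
from dendropy.simulate import treesim

from mycoverlap import HostIncidence, PhyloTree
from mycoverlap.datasets import load_small_fixture

# 4-leaf balanced reference tree: every edge length 1, total length 6
FIXTURE4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def tree4() -> PhyloTree:
    return PhyloTree.from_newick(FIXTURE4)


@pytest.fixture
def inc23() -> HostIncidence:
    # two plants, three fungi: host sets {f1,f2} and {f2,f3}
    return HostIncidence(["p1", "p2"], ["f1", "f2", "f3"], [[1, 1, 0], [0, 1, 1]])


def make_random_tree(rng: random.Random, n_leaves: int) -> PhyloTree:
    """Random topology with uniform(0.05, 2) branch lengths."""
    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves, rng=rng
    )
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = rng.uniform(0.05, 2.0)
    return PhyloTree.from_dendropy(dtree)


@pytest.fixture
def random_tree_factory():
    return make_random_tree


def brute_force_pd_extremes(tree: PhyloTree, k: int) -> tuple[float, float]:
    """Exhaustive (min, max) PD over all k-subsets — the independent oracle."""
    from itertools import combinations

    M = tree.leaf_matrix
    bl = tree.branch_length
    lo, hi = np.inf, -np.inf
    for comb in combinations(range(tree.n_leaves), k):
        counts = M[:, list(comb)].sum(axis=1)
        pd = bl[(counts >= 1) & (counts < k)].sum()
        lo, hi = min(lo, pd), max(hi, pd)
    return float(lo), float(hi)


@pytest.fixture(scope="session")
def small_fixture():
    """The shipped 6-plant x 20-fungus synthetic dataset."""
    return load_small_fixture()
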