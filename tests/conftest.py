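import numpy as np
import pytest

from pemtrait.phylo_graph import PhyloTree, parse_newick
from pemtrait.synthetic_data import SimulationConfig, simulate_tree


def random_tree(seed: int, n_tips: int, integer_lengths: bool = False) -> PhyloTree:
    """A random tree for property tests; optionally with integer branch
    lengths so Gram-matrix identities hold exactly."""
    config = SimulationConfig(seed=seed, n_tips=max(4, n_tips), fossil_fraction=0.0)
    tree = simulate_tree(config)
    if integer_lengths:
        rng = np.random.default_rng(seed + 10_000)
        for node in tree.preorder():
            if node.parent is not None:
                node.length = float(rng.integers(1, 10))
    return tree


@pytest.fixture
def caterpillar():
    # ((A:1,B:2):3,C:4); the worked example used across modules
    return parse_newick("((A:1,B:2):3,C:4);")


@pytest.fixture
def two_tip():
    return parse_newick("(A:1,B:1);")
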