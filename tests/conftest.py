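import numpy as np
import pytest

import phylotempo as pt


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — depths: A,B,C all 2; MRCA(A,B) at depth 1."""
    return pt.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return pt.parse_newick("(" + ",".join(f"s{i}:1" for i in range(12)) + ");")


@pytest.fixture
def yule30():
    return pt.simulate_yule_tree(30, 1.0, seed=42)


@pytest.fixture
def bm_traits30(yule30):
    return pt.simulate_bm_traits(yule30, pt.SimulationSpec(n_tips=30, seed=7))


def random_small_instance(rng: np.random.Generator, max_tips: int = 10):
    """A random (tree, trait) pair for oracle comparisons."""
    n = int(rng.integers(3, max_tips + 1))
    tree = pt.simulate_yule_tree(n, 1.0, seed=int(rng.integers(2**31)))
    y = pt.simulate_bm_traits(
        tree, pt.SimulationSpec(n_tips=n, seed=int(rng.integers(2**31)))
    )
    return tree, y
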