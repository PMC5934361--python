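import numpy as np
import pytest

from latdiv import simulate as sim
from latdiv import treeio


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — ultrametric, root age 2 my."""
    return treeio.read_tree("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def cherry_tree():
    """(A:1,B:1); — the 2-tip worked-example tree."""
    return treeio.read_tree("(A:1,B:1):0;")


@pytest.fixture(scope="session")
def yule_tree_50():
    """50-tip pure-birth tree rescaled to a 100-my root."""
    tree = sim.simulate_tree(n_tips=50, birth=0.05, seed=1001)
    return sim.scale_to_age(tree, 100.0)


@pytest.fixture(scope="session")
def eight_tip_fixture():
    """8-tip tree (100-my root) with a slowly evolving binary trait."""
    tree = sim.scale_to_age(sim.simulate_tree(n_tips=8, birth=0.05, seed=11), 100.0)
    states, truth = sim.simulate_binary_trait(tree, 0.01, 0.01, seed=12)
    return tree, states, truth


def random_tree(rng, n_min=4, n_max=10, death=0.0):
    n = int(rng.integers(n_min, n_max + 1))
    return sim.simulate_tree(n_tips=n, birth=0.2, death=death,
                             seed=int(rng.integers(2**31)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
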