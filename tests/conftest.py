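import numpy as np
import pytest

from paleorange import RangeStateSpace, read_newick
from paleorange.simulate import SimParams, simulate_tree

SINGLES = ("SA", "NA", "EU", "AF")


@pytest.fixture(scope="session")
def space():
    """Reconstruction state space: 4 areas, ranges up to 3 continents."""
    return RangeStateSpace(max_range_size=3)


@pytest.fixture(scope="session")
def sim_space():
    """Simulation state space: ranges capped at 2 adjacent continents."""
    return RangeStateSpace(max_range_size=2)


def bound_tree(newick, ranges):
    """Parse a Newick string and attach tip ranges from a dict of sets."""
    tree = read_newick(newick)
    for tip in tree.tips():
        tip.range_ = frozenset(ranges[tip.name])
    return tree


def random_small_tree(rng, n_tips=None):
    """Random 2-4 tip tree with random lengths and singleton tip ranges."""
    n = n_tips or rng.integers(2, 5)
    shapes = {
        2: "(A:{0},B:{1});",
        3: "((A:{0},B:{1}):{2},C:{3});",
        4: rng.choice(
            [
                "(((A:{0},B:{1}):{2},C:{3}):{4},D:{5});",
                "((A:{0},B:{1}):{2},(C:{3},D:{4}):{5});",
            ]
        ),
    }[n]
    lengths = rng.uniform(0.1, 3.0, 6)
    tree = read_newick(shapes.format(*lengths))
    for tip in tree.tips():
        tip.range_ = frozenset({SINGLES[rng.integers(4)]})
    return tree


#: moderate-turnover rates used for quick simulated-tree fixtures
QUICK_SIM = SimParams(mu=0.2, delta=0.1, lambda1=0.3, lambda2=0.05, lambda3=0.5)


@pytest.fixture(scope="session")
def sim_result():
    """One ~50-extant-tip simulated tree with extinct tips and truth ranges."""
    return simulate_tree(QUICK_SIM, 50, seed=421)


@pytest.fixture
def rng():
    return np.random.default_rng(987)
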