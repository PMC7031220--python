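import pytest

from paleopop import (
    SamplingDesign,
    TimedTree,
    make_ne_trajectory,
    simulate_genealogy,
)


@pytest.fixture(scope="session")
def constant_traj():
    return make_ne_trajectory("constant", base_ne=1000.0)


@pytest.fixture(scope="session")
def balanced_four_tip_tree():
    """((A1,A2),(B1,B2)) with all tips contemporaneous, unit heights."""
    newick = "((A1:1,A2:1):1,(B1:1,B2:1):1);"
    dates = {t: 2000.0 for t in ("A1", "A2", "B1", "B2")}
    return TimedTree.from_newick(newick, 2000.0, dates)


@pytest.fixture(scope="session")
def fifty_tip_tree(constant_traj):
    design = SamplingDesign("S", ((2000.0, 50),))
    return simulate_genealogy(design, constant_traj, seed=12345)

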