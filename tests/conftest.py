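import warnings

import pytest

from phylocons import simulate, treeio

warnings.filterwarnings("ignore", message="zero-length branch")


@pytest.fixture
def three_tip_tree() -> treeio.TimeTree:
    """((A:1,B:1):1,C:2); total length 5, ultrametric at height 2."""
    return treeio.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def vulture():
    """(tree, two_area_coding, three_area_coding, categories) fixture clade."""
    return simulate.vulture_fixture()


@pytest.fixture(scope="session")
def yule_trees():
    """100 small random Yule trees for property assertions."""
    return [
        simulate.simulate_yule_tree(n, birth_rate=1.0, seed=1000 + i)
        for i, n in enumerate([5, 8, 13, 21, 34] * 20)
    ]
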