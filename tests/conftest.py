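import numpy as np
import pytest

from orthotrim.trees import ArrayTree


@pytest.fixture
def balanced_tree() -> ArrayTree:
    return ArrayTree.from_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.4):0.6);")


@pytest.fixture
def eight_tip_tree() -> ArrayTree:
    newick = (
        "((((s01:0.1,s02:0.1):0.1,s03:0.1):0.1,s04:0.1):0.1,"
        "(((s05:0.1,s06:0.1):0.1,s07:0.1):0.1,s08:0.1):0.1);"
    )
    return ArrayTree.from_newick(newick)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
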