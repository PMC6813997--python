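import numpy as np
import pytest

import phyloconv as pc


@pytest.fixture
def cherry():
    return pc.read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return pc.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four():
    return pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_tree():
    return pc.simulate_tree(16, 36.0, seed=11)
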