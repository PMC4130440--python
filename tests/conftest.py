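import numpy as np
import pandas as pd
import pytest

import traitevo as te


@pytest.fixture(scope="session")
def balanced4():
    """Balanced 4-tip tree with unit branches: V = [[2,1,0,0],[1,2,0,0],...]."""
    tree = te.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    tree.date_from_branch_lengths()
    return tree


@pytest.fixture(scope="session")
def tree50():
    return te.simulate_tree(n_tips=50, root_age=100.0, seed=501)


@pytest.fixture(scope="session")
def tree200():
    return te.simulate_tree(n_tips=200, root_age=100.0, seed=2001)


def series_on(tree, values):
    return pd.Series(np.asarray(values, dtype=float), index=tree.tip_labels)


@pytest.fixture
def pi_traits():
    def make(tree, seed, mean=4.0, sd=1.0):
        rng = np.random.default_rng(seed)
        return series_on(tree, rng.normal(mean, sd, tree.n_tips))

    return make
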