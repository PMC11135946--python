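import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from molclock.tree import parse_newick


@pytest.fixture
def balanced_tree():
    return parse_newick(
        "((A:1000,B:1000):2000,((C:500,D:500):1500,(E:800,(F:400,"
        "(G:150,H:150):250):400):1200):1000);")


@pytest.fixture
def quartet():
    return parse_newick("((A:1000,B:1000):2000,(C:500,D:500):2500);")


@pytest.fixture
def rng():
    return np.random.default_rng(20231201)
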