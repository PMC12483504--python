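import numpy as np
import pytest

import nrevphylo as nv
from nrevphylo.trees import RootedTree


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def quartet_tree():
    return RootedTree.from_newick("((A:0.2,B:0.35):0.1,(C:0.15,D:0.4):0.25);")


@pytest.fixture(scope="session")
def baseline_q():
    """The reversible simulation baseline generator (unnormalized)."""
    return nv.build_nrev12_q(nv.ladder_rates(0.0))


def random_positive_rates12(rng, low=0.05, high=3.0):
    return rng.uniform(low, high, size=12)


@pytest.fixture(scope="session")
def random_generators(rng):
    """A mix of GTR, NREV6 and NREV12 generators for property checks."""
    gens = []
    for k in range(6):
        pi = rng.dirichlet(np.ones(4) * 5)
        gens.append(nv.build_gtr_q(rng.uniform(0.1, 2.0, 6), nv.BaseFrequencies(pi)))
        gens.append(nv.build_nrev6_q(rng.uniform(0.1, 2.0, 6)))
        gens.append(nv.build_nrev12_q(random_positive_rates12(rng)))
    return gens
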