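import numpy as np
import pytest

from phylosel import Phylogeny, read_newick, simulate_tree


@pytest.fixture(scope="session")
def three_tip_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); — depths 2, cov(A,B)=1, cov(.,C)=0."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree64() -> Phylogeny:
    return simulate_tree(64, "pure_birth", 1.0, seed=7)


@pytest.fixture(scope="session")
def tree12() -> Phylogeny:
    return simulate_tree(12, "pure_birth", 1.0, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
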