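import numpy as np
import pytest

from caulotraits import DimorphicParams, simulate_lineage
from caulotraits.trees import Phylogeny, random_coalescent_tree


@pytest.fixture
def small_tree() -> Phylogeny:
    """((A,B),(C,D)); — the smallest tree with two sister clades."""
    return Phylogeny.from_newick("((A,B),(C,D));")


@pytest.fixture
def caterpillar() -> Phylogeny:
    return Phylogeny.from_newick("(((A,B),C),D);")


@pytest.fixture
def random_trees():
    def make(n_trees: int, n_tips: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        return [
            random_coalescent_tree(int(rng.integers(3, n_tips + 1)), rng)
            for _ in range(n_trees)
        ]

    return make


@pytest.fixture
def dimorphic_table():
    """A standard dimorphic simulation shared by lifecycle tests."""
    return simulate_lineage(
        DimorphicParams(duration=480, n_founders=20, seed=11)
    )
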