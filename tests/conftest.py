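import numpy as np
import pytest

from islandtraits import phylo
from islandtraits import synthetic_data as sd


@pytest.fixture
def toy_tree():
    """Balanced 4-tip ultrametric tree of height 2, all branches length 1."""
    return phylo.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def tree_factory():
    """Seeded Yule-tree factory: tree_factory(n, seed) -> Phylogeny."""

    def make(n, seed=0, birth=0.1, death=0.0):
        return sd.simulate_tree(n, birth=birth, death=death, seed=seed)

    return make


@pytest.fixture
def bm_data(tree_factory):
    """A 30-tip tree with one BM trait, as (tree, values array, mapping)."""
    tree = tree_factory(30, seed=11)
    tips, _ = sd.simulate_trait(tree, "BM", {"sigma2": 0.5, "z0": 0.0}, seed=12)
    vals = np.array([tips[l] for l in tree.tip_labels])
    return tree, vals, tips
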