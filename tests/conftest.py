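import numpy as np
import pytest

from gmyc import UltrametricTree
from gmyc.simulate import simulate_msc_gene_tree, simulate_yule_species_tree

CHERRY3 = "((A:1,B:1):1,C:2);"
LADDER4 = "(((A:1,B:1):1,C:2):1,D:3);"
BALANCED6 = "(((a:1,b:1):3,(c:2,d:2):2):4,(e:3,f:3):5);"


@pytest.fixture
def cherry3():
    return UltrametricTree.from_newick(CHERRY3)


@pytest.fixture
def ladder4():
    return UltrametricTree.from_newick(LADDER4)


@pytest.fixture
def balanced6():
    return UltrametricTree.from_newick(BALANCED6)


@pytest.fixture(scope="session")
def small_sim_trees():
    """Simulated MSC gene trees of 6-9 tips for oracle comparisons."""
    trees = []
    for seed in range(4):
        sp = simulate_yule_species_tree(6, 3, depth=8.0, seed=100 + seed)
        gt = simulate_msc_gene_tree(sp, np.array([3, 2, 2]), seed=200 + seed)
        trees.append(gt)
    return trees


@pytest.fixture(scope="session")
def medium_sim_tree():
    """A 50-tip gene tree (10 species x 5 alleles, depth 80 N)."""
    sp = simulate_yule_species_tree(30, 10, depth=80.0, seed=7)
    return simulate_msc_gene_tree(sp, np.full(10, 5), seed=8)


@pytest.fixture(scope="session")
def deep_sim_tree():
    """A 250-tip gene tree under the deep (160 N) study condition."""
    sp = simulate_yule_species_tree(150, 50, depth=160.0, seed=42)
    return simulate_msc_gene_tree(sp, np.full(50, 5), seed=43)
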