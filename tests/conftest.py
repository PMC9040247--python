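import numpy as np
import pytest

from phylodiscord import msc_sim, treekit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def caterpillar6():
    return treekit.parse_newick("(((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5);")


@pytest.fixture
def balanced4():
    return treekit.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_binary_tree(labels, rng, with_lengths=True):
    """Random rooted binary tree by sequential random attachment."""
    labels = list(labels)
    rng.shuffle(labels)
    nodes = [treekit.Node(lab) for lab in labels[:2]]
    root = treekit.Node()
    for n in nodes:
        root.add_child(n)
    for lab in labels[2:]:
        # pick a random non-root node and split its parent edge
        candidates = [n for n in root.postorder() if n is not root]
        target = candidates[rng.integers(len(candidates))]
        parent = target.parent
        mid = treekit.Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        mid.add_child(treekit.Node(lab))
    tree = treekit.Tree(root, validate=False)
    if with_lengths:
        for n in tree.root.postorder():
            if n is not tree.root:
                n.length = float(rng.uniform(0.05, 2.0))
    tree.validate()
    return tree


@pytest.fixture
def make_random_tree(rng):
    def _make(labels, with_lengths=True):
        return random_binary_tree(labels, rng, with_lengths)
    return _make


@pytest.fixture(scope="session")
def focal_branch_trees():
    """Gene trees from a species tree whose only short branch is T=1 coalescent
    units (AB|rest); all other internal branches are long enough that other
    discordance is negligible.  Shared across concordance/spectrum tests."""
    scenario = msc_sim.Scenario(
        species_tree=treekit.parse_newick("((((A:1,B:1):1,C:2):8,D:10):8,O:18);"),
        outgroup="O", loci=6000, seed=42, coal_scale=1.0)
    return scenario, msc_sim.simulate_gene_trees(scenario)
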