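import numpy as np
import pytest

from cogevo import simulate_taxonomy, wag, poisson_model
from cogevo.taxa import Category, TaxonRecord, TaxonSet


@pytest.fixture(scope="session")
def wag_model():
    return wag()


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


@pytest.fixture(scope="session")
def small_taxa():
    """Six taxa per reference category (30 total)."""
    return simulate_taxonomy(
        {c: 6 for c in list(Category) if c is not Category.FOCAL}, seed=1)


@pytest.fixture(scope="session")
def taxonomy_with_focal(small_taxa):
    return TaxonSet(list(small_taxa)
                    + [TaxonRecord("FOCAL", "focal organism", Category.FOCAL)])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_binary_tree(labels, rng, length_low=0.1, length_high=1.0):
    """Random unrooted binary tree with uniform branch lengths (test oracle
    helper, independent of neighbour joining)."""
    from cogevo.tree import PhyloTree
    t = PhyloTree()
    nodes = [t.add_node(lab) for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = t.add_node()
        t.add_edge(parent, a, float(rng.uniform(length_low, length_high)))
        t.add_edge(parent, b, float(rng.uniform(length_low, length_high)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    t.add_edge(nodes[0], nodes[1], float(rng.uniform(length_low, length_high)))
    t.suppress_degree_two()
    return t


def tree_distance_matrix(tree):
    """Leaf-to-leaf path-length matrix (order = sorted leaf names)."""
    import numpy as np
    names = sorted(tree.leaf_names)
    n = len(names)
    d = np.zeros((n, n))
    for i, a in enumerate(names):
        dist = tree.path_lengths_from(tree.node_of(a))
        for j, b in enumerate(names):
            d[i, j] = dist[tree.node_of(b)]
    return names, d
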