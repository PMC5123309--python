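import itertools

import numpy as np
import pytest

from distique import Tree, random_species_tree


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_binary_tree(n, rng, length_range=(0.05, 2.0)):
    """Random edge-weighted binary unrooted tree (test helper)."""
    return random_species_tree(n, rng, length_range).tree


def all_binary_topologies(labels):
    """Enumerate every labeled unrooted binary topology on the given leaves
    by sequential attachment — (2n-5)!! trees.  Brute-force oracle."""
    labels = sorted(labels)
    base = Tree()
    c = base.add_node()
    for lab in labels[:3]:
        base.add_edge(c, base.add_node(lab))
    trees = [base]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            for a, b, _ in t.edges():
                t2 = t.copy()
                t2.remove_edge(a, b)
                mid = t2.add_node()
                t2.add_edge(a, mid)
                t2.add_edge(mid, b)
                t2.add_edge(mid, t2.add_node(lab))
                nxt.append(t2)
        trees = nxt
    return trees


def quartet_topology_from_tree(tree, a, b, c, d):
    """Sister pair of {a,b,c,d} in the tree via restriction; None if
    unresolved.  Independent of path_attachment."""
    sub = tree.restrict([a, b, c, d])
    bips = sub.bipartitions()
    if not bips:
        return None
    side = next(iter(bips))
    return frozenset(side)
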