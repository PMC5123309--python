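"""Species-tree and multi-species-coalescent gene-tree simulation.

Species trees carry branch lengths in coalescent units (generations divided
by effective population size) and one sampled lineage per species.  Gene
trees are drawn by running the standard coalescent within each species-tree
branch: with j lineages present, the waiting time to the next coalescence is
exponential with rate j(j-1)/2, the merging pair is uniform, and all
remaining lineages coalesce above the root.  For an unrooted species-tree
quartet with internal length tau this yields the classic quartet law:
concordant topology with probability 1 - (2/3) e^-tau, each discordant one
with probability (1/3) e^-tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .trees import Tree


@dataclass
class SpeciesTreeModel:
    """A binary unrooted species tree with all branch lengths positive, in
    coalescent units."""

    tree: Tree

    def __post_init__(self) -> None:
        if not self.tree.is_binary:
            raise ValueError("species tree must be binary")
        for a, b, ln in self.tree.edges():
            if ln is None or ln <= 0:
                raise ValueError("species tree branch lengths must be positive")


def default_labels(n: int) -> List[str]:
    width = max(2, len(str(n)))
    return [f"t{i:0{width}d}" for i in range(1, n + 1)]


def random_species_tree(n: int, rng: np.random.Generator,
                        length_range: Tuple[float, float] = (0.5, 2.0)
                        ) -> SpeciesTreeModel:
    """Uniformly random binary topology on n leaves (sequential attachment
    to a uniformly chosen edge) with i.i.d. uniform branch lengths."""
    if n < 4:
        raise ValueError("need at least 4 species")
    lo, hi = length_range
    if not (0 < lo < hi):
        raise ValueError("invalid length range")
    labels = default_labels(n)
    t = Tree()
    center = t.add_node()
    for lab in labels[:3]:
        t.add_edge(center, t.add_node(lab))
    for lab in labels[3:]:
        edges = t.edges()
        a, b, _ = edges[int(rng.integers(len(edges)))]
        t.remove_edge(a, b)
        mid = t.add_node()
        t.add_edge(a, mid)
        t.add_edge(mid, b)
        t.add_edge(mid, t.add_node(lab))
    for a, b, _ in t.edges():
        t._adj[a][b] = t._adj[b][a] = float(rng.uniform(lo, hi))
    return SpeciesTreeModel(t)


def _rooted_view(tree: Tree) -> Tuple[object, Dict[int, List[Tuple[int, float]]]]:
    """Root the unrooted species tree on its first internal edge (the MSC
    gene-tree distribution over unrooted topologies does not depend on the
    root placement).  Returns (root marker, children map node ->
    [(child, branch length into child)])."""
    internal = tree.internal_edges()
    if internal:
        ra, rb = internal[0]
    else:  # n == 4 caterpillar-free case cannot happen; quartets have one
        ra, rb = tree.edges()[0][:2]
    length = tree.edge_length(ra, rb)
    root = -1
    children: Dict[int, List[Tuple[int, float]]] = {root: [(ra, length / 2.0),
                                                           (rb, length / 2.0)]}

    def fill(node: int, parent: int) -> None:
        children[node] = []
        for w in tree.neighbors(node):
            if w == parent:
                continue
            children[node].append((w, tree.edge_length(node, w)))
            fill(w, node)

    fill(ra, rb)
    fill(rb, ra)
    return root, children


def _coalesce(lineages: List[int], length: float, gene: Tree,
              rng: np.random.Generator) -> List[int]:
    t = 0.0
    lineages = list(lineages)
    while len(lineages) >= 2:
        j = len(lineages)
        t += rng.exponential(1.0 / (j * (j - 1) / 2.0))
        if t > length:
            break
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        new = gene.add_node()
        gene.add_edge(lineages[i1], new)
        gene.add_edge(lineages[i2], new)
        lineages[i1] = new
        del lineages[i2]
    return lineages


def simulate_gene_trees(model: SpeciesTreeModel, k: int,
                        rng: np.random.Generator) -> List[Tree]:
    """Draw k independent gene trees (unrooted topologies, no lengths)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    stree = model.tree
    root, children = _rooted_view(stree)
    # post-order over the rooted view
    order: List[int] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(c for c, _ in children.get(node, []))
    order.reverse()

    out: List[Tree] = []
    for _ in range(k):
        gene = Tree()
        surviving: Dict[int, List[int]] = {}
        for node in order:
            kids = children.get(node, [])
            if not kids:  # species leaf: one sampled lineage
                lab = stree.label_of(node)
                surviving[node] = [gene.add_node(lab)]
                continue
            pool: List[int] = []
            for child, length in kids:
                pool.extend(_coalesce(surviving.pop(child), length, gene, rng))
            surviving[node] = pool
        pool = surviving[root]
        while len(pool) > 1:  # full coalescence above the root
            pool = _coalesce(pool, math.inf, gene, rng)
        gene.suppress_degree_two()
        out.append(gene)
    return out


def quartet_concordance_prob(tau: float) -> float:
    """MSC probability that a gene tree shows the species-tree quartet
    topology, for internal branch length tau > 0: 1 - (2/3) e^-tau."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return 1.0 - (2.0 / 3.0) * math.exp(-tau)
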