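"""Majority-rule consensus, polytomy contexts, and grafting resolutions.

Long species-tree branches saturate quartet frequencies (many different long
lengths all yield near-zero discordance), so distances cannot rank them —
but precisely because they are long, they appear in most gene trees.  The
pipeline therefore takes the strict-majority (>50%) consensus of the gene
trees, which recovers long branches directly, and only uses anchored
distances to resolve the consensus polytomies.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence

from .trees import Tree, TreeError, star, tree_from_bipartitions

#: Prefix for cluster labels so they cannot collide with species names.
CLUSTER_PREFIX = "@"


def majority_consensus(gene_trees: Sequence[Tree]) -> Tree:
    """Tree containing exactly the bipartitions found in strictly more than
    half of the gene trees (such bipartitions are mutually compatible).
    All trees must share one leaf set."""
    if not gene_trees:
        raise TreeError("no gene trees")
    leaf_set = gene_trees[0].leaf_set
    for t in gene_trees[1:]:
        if t.leaf_set != leaf_set:
            raise TreeError("gene trees must share a leaf set for consensus")
    k = len(gene_trees)
    counts: Counter = Counter()
    for t in gene_trees:
        counts.update(t.bipartitions())
    majority = [bp for bp, c in counts.items() if 2 * c > k]
    return tree_from_bipartitions(leaf_set, majority)


@dataclass
class PolytomyContext:
    """One unresolved consensus node and the clusters hanging off it.

    ``clusters`` maps a synthetic cluster label (``@`` + smallest leaf of
    the cluster) to the set of leaves behind the corresponding pendant edge;
    the clusters partition the full leaf set.  ``edge_nodes`` maps each
    cluster label to the neighboring node id in the consensus tree.
    """

    node: int
    degree: int
    clusters: Dict[str, FrozenSet[str]]
    edge_nodes: Dict[str, int] = field(default_factory=dict)

    def cluster_of(self, leaf: str) -> str:
        for lab, members in self.clusters.items():
            if leaf in members:
                return lab
        raise KeyError(leaf)


def polytomy_contexts(consensus: Tree) -> List[PolytomyContext]:
    """One context per internal node of degree >= 4, in sorted node order."""
    out: List[PolytomyContext] = []
    for node in consensus.polytomy_nodes():
        clusters: Dict[str, FrozenSet[str]] = {}
        edge_nodes: Dict[str, int] = {}
        for w in consensus.neighbors(node):
            members = consensus.leaves_behind(node, w)
            lab = CLUSTER_PREFIX + min(members)
            clusters[lab] = members
            edge_nodes[lab] = w
        out.append(PolytomyContext(node=node, degree=consensus.degree(node),
                                   clusters=clusters, edge_nodes=edge_nodes))
    return out


def graft_resolution(consensus: Tree, context: PolytomyContext,
                     resolved: Tree) -> Tree:
    """Replace a polytomy with a resolution given on its cluster labels.

    ``resolved`` must be an unrooted tree whose leaves are exactly the
    cluster labels of ``context``.  Pendant edges keep their consensus
    branch lengths; new internal edges carry none.  The rest of the
    consensus (including other polytomies and their node ids) is untouched.
    """
    if resolved.leaf_set != frozenset(context.clusters):
        raise TreeError("resolution leaves do not match the polytomy clusters")
    t = consensus.copy()
    z = context.node
    # re-derive the cluster -> neighbor map from the current tree: grafting
    # an adjacent polytomy may have replaced a neighbor node, but the leaf
    # set behind each pendant edge is invariant
    edge_nodes: Dict[str, int] = {}
    for w in t.neighbors(z):
        members = t.leaves_behind(z, w)
        edge_nodes[CLUSTER_PREFIX + min(members)] = w
    if set(edge_nodes) != set(context.clusters):
        raise TreeError("tree no longer matches the polytomy context")
    context = PolytomyContext(node=z, degree=context.degree,
                              clusters=context.clusters, edge_nodes=edge_nodes)
    pendant_length = {lab: t.edge_length(z, nbr)
                      for lab, nbr in context.edge_nodes.items()}
    t.remove_node(z)
    # map resolution nodes into the consensus: internal -> fresh node,
    # leaf (cluster label) -> the neighbor node its subtree hangs from
    node_map: Dict[int, int] = {}
    for rn in resolved.nodes:
        if resolved.is_leaf(rn):
            node_map[rn] = context.edge_nodes[resolved.label_of(rn)]
        else:
            node_map[rn] = t.add_node()
    for a, b, _ in resolved.edges():
        length = None
        for side in (a, b):
            if resolved.is_leaf(side):
                length = pendant_length[resolved.label_of(side)]
        t.add_edge(node_map[a], node_map[b], length)
    t.suppress_degree_two()
    return t
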