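"""Unrooted leaf-labelled trees and the structural queries the estimator needs.

The tree is stored as a plain adjacency map over integer node ids, with
optional non-negative branch lengths on edges and unique string labels on
leaves.  Everything downstream (quartet frequencies, consensus, grafting,
neighbor joining) treats trees as unrooted; rooted newick input is unrooted
on read.  Newick parsing is delegated to dendropy.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

import dendropy


class TreeError(ValueError):
    """Structural error on a tree operation."""


class NewickParseError(TreeError):
    """Malformed newick input."""


Bipartition = FrozenSet[str]
#: A non-trivial bipartition, represented canonically by the side that does
#: not contain the lexicographically smallest leaf label of the tree.


class Tree:
    """Unrooted, possibly multifurcating, leaf-labelled tree."""

    __slots__ = ("_adj", "_labels", "_by_label", "_next")

    def __init__(self) -> None:
        self._adj: Dict[int, Dict[int, Optional[float]]] = {}
        self._labels: Dict[int, str] = {}
        self._by_label: Dict[str, int] = {}
        self._next = 0

    # ------------------------------------------------------------------ build

    def add_node(self, label: Optional[str] = None) -> int:
        node = self._next
        self._next += 1
        self._adj[node] = {}
        if label is not None:
            if label in self._by_label:
                raise TreeError(f"duplicate leaf label {label!r}")
            self._labels[node] = label
            self._by_label[label] = node
        return node

    def add_edge(self, a: int, b: int, length: Optional[float] = None) -> None:
        if a == b or b in self._adj[a]:
            raise TreeError("invalid edge")
        if length is not None and length < 0:
            raise TreeError("negative branch length")
        self._adj[a][b] = length
        self._adj[b][a] = length

    def remove_edge(self, a: int, b: int) -> None:
        del self._adj[a][b]
        del self._adj[b][a]

    def remove_node(self, node: int) -> None:
        for w in list(self._adj[node]):
            self.remove_edge(node, w)
        del self._adj[node]
        label = self._labels.pop(node, None)
        if label is not None:
            del self._by_label[label]

    def copy(self) -> "Tree":
        t = Tree.__new__(Tree)
        t._adj = {v: dict(nb) for v, nb in self._adj.items()}
        t._labels = dict(self._labels)
        t._by_label = dict(self._by_label)
        t._next = self._next
        return t

    # ------------------------------------------------------------ inspection

    @property
    def nodes(self) -> List[int]:
        return sorted(self._adj)

    @property
    def leaves(self) -> List[str]:
        return sorted(self._by_label)

    @property
    def leaf_set(self) -> FrozenSet[str]:
        return frozenset(self._by_label)

    @property
    def n_leaves(self) -> int:
        return len(self._by_label)

    def is_leaf(self, node: int) -> bool:
        return node in self._labels

    def label_of(self, node: int) -> str:
        return self._labels[node]

    def node_of(self, label: str) -> int:
        try:
            return self._by_label[label]
        except KeyError:
            raise TreeError(f"unknown leaf {label!r}") from None

    def degree(self, node: int) -> int:
        return len(self._adj[node])

    def neighbors(self, node: int) -> List[int]:
        return sorted(self._adj[node])

    def edge_length(self, a: int, b: int) -> Optional[float]:
        return self._adj[a][b]

    def edges(self) -> List[Tuple[int, int, Optional[float]]]:
        """Edges as (a, b, length) with a < b, sorted."""
        out = []
        for a in sorted(self._adj):
            for b, ln in sorted(self._adj[a].items()):
                if a < b:
                    out.append((a, b, ln))
        return out

    def internal_edges(self) -> List[Tuple[int, int]]:
        return [(a, b) for a, b, _ in self.edges()
                if not self.is_leaf(a) and not self.is_leaf(b)]

    @property
    def is_binary(self) -> bool:
        """Unrooted-binary: every internal node has degree exactly 3."""
        for node in self._adj:
            if not self.is_leaf(node) and self.degree(node) != 3:
                return False
        return True

    def polytomy_nodes(self) -> List[int]:
        return [v for v in self.nodes if not self.is_leaf(v) and self.degree(v) >= 4]

    # --------------------------------------------------------------- queries

    def leaves_behind(self, node: int, through: int) -> FrozenSet[str]:
        """Leaf labels in the component containing `through` when the
        edge (node, through) is removed."""
        seen = {node, through}
        out: List[str] = []
        stack = [through]
        while stack:
            x = stack.pop()
            if self.is_leaf(x):
                out.append(self._labels[x])
            for w in self._adj[x]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return frozenset(out)

    def node_path(self, a: int, b: int) -> List[int]:
        """Unique simple path from node a to node b (inclusive)."""
        parent: Dict[int, int] = {a: a}
        q = deque([a])
        while q:
            x = q.popleft()
            if x == b:
                break
            for w in self._adj[x]:
                if w not in parent:
                    parent[w] = x
                    q.append(w)
        if b not in parent:
            raise TreeError("nodes not connected")
        path = [b]
        while path[-1] != a:
            path.append(parent[path[-1]])
        return path[::-1]

    def path_attachment(self, u: str, v: str) -> Dict[str, Tuple[int, int]]:
        """Hang-off tokens of every other leaf relative to the u--v path.

        Returns, for each leaf x not in {u, v}, the token
        ``(path index, off-path neighbor node)`` identifying the path vertex
        and off-path edge through which x attaches to the u--v path.  For any
        two leaves a, b the induced quartet on {a, b, u, v} is ab.uv iff
        their tokens are equal; it is unresolved iff the tokens share the
        path index but not the edge (possible only at polytomies).
        Linear time in the tree size.
        """
        if u == v:
            raise TreeError("anchors must be distinct")
        nu, nv = self.node_of(u), self.node_of(v)
        path = self.node_path(nu, nv)
        on_path = set(path)
        tokens: Dict[str, Tuple[int, int]] = {}
        for i, p in enumerate(path):
            for w in self._adj[p]:
                if w in on_path:
                    continue
                for lab in self.leaves_behind(p, w):
                    tokens[lab] = (i, w)
        return tokens

    # -------------------------------------------------------------- editing

    def suppress_degree_two(self) -> None:
        """Remove unlabelled degree-2 nodes, summing branch lengths."""
        for node in list(self._adj):
            if node in self._adj and not self.is_leaf(node) and self.degree(node) == 2:
                (a, la), (b, lb) = sorted(self._adj[node].items())
                length = None if (la is None and lb is None) else (la or 0.0) + (lb or 0.0)
                self.remove_node(node)
                if b not in self._adj[a]:
                    self.add_edge(a, b, length)

    def restrict(self, labels: Iterable[str]) -> "Tree":
        """Induced tree on a leaf subset; degree-2 nodes suppressed with
        adjacent branch lengths summed."""
        keep = set(labels)
        unknown = keep - self.leaf_set
        if unknown:
            raise TreeError(f"unknown leaves {sorted(unknown)}")
        if len(keep) < 3:
            raise TreeError("restriction needs at least 3 leaves")
        t = self.copy()
        for lab in sorted(t.leaf_set - keep):
            t.remove_node(t.node_of(lab))
        # prune dangling unlabelled nodes, then suppress pass-through nodes
        changed = True
        while changed:
            changed = False
            for node in list(t._adj):
                if node in t._adj and not t.is_leaf(node) and t.degree(node) <= 1:
                    t.remove_node(node)
                    changed = True
        t.suppress_degree_two()
        return t

    # ----------------------------------------------------------- bipartition

    def bipartitions(self) -> Set[Bipartition]:
        """Non-trivial bipartitions, one per internal edge, each represented
        by the side not containing the smallest leaf label."""
        if self.n_leaves < 4:
            return set()
        ref = min(self._by_label)
        out: Set[Bipartition] = set()
        for a, b in self.internal_edges():
            side = self.leaves_behind(a, b)
            if len(side) < 2 or self.n_leaves - len(side) < 2:
                continue
            if ref in side:
                side = self.leaf_set - side
            out.add(side)
        return out

    # ------------------------------------------------------------------- I/O

    def to_newick(self, lengths: bool = True) -> str:
        """Deterministic newick: traversal rooted next to the smallest leaf,
        children ordered by smallest contained label."""
        if self.n_leaves == 0:
            return ";"
        if self.n_leaves == 1:
            return next(iter(self._by_label)) + ";"
        start_leaf = self.node_of(min(self._by_label))
        root = self.neighbors(start_leaf)[0]

        def min_label(node: int, parent: int) -> str:
            if self.is_leaf(node):
                return self._labels[node]
            return min(min_label(w, node) for w in self._adj[node] if w != parent)

        def fmt(node: int, parent: int) -> str:
            ln = self._adj[node][parent]
            suffix = "" if (ln is None or not lengths) else f":{ln:.10g}"
            if self.is_leaf(node):
                return self._labels[node] + suffix
            kids = sorted((w for w in self._adj[node] if w != parent),
                          key=lambda w: min_label(w, node))
            return "(" + ",".join(fmt(w, node) for w in kids) + ")" + suffix

        kids = sorted(self._adj[root], key=lambda w: min_label(w, root))
        return "(" + ",".join(fmt(w, root) for w in kids) + ");"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree n={self.n_leaves}>"


# ---------------------------------------------------------------- parse/write


def parse_newick(text: str) -> Tree:
    """Parse one newick string into an unrooted :class:`Tree`.

    Quoted labels and bracket comments are tolerated (dendropy dialect);
    rooted inputs (bifurcating root) are unrooted by merging the two root
    edges.  Raises :class:`NewickParseError` on malformed input and
    :class:`TreeError` on duplicate leaf labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except TreeError:
        raise
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc

    t = Tree()
    node_map: Dict[int, int] = {}
    for dnode in dtree.preorder_node_iter():
        label = None
        if dnode.is_leaf():
            if dnode.taxon is None or dnode.taxon.label is None:
                raise NewickParseError("leaf without a label")
            label = dnode.taxon.label
        node_map[id(dnode)] = t.add_node(label)
    for dnode in dtree.preorder_node_iter():
        if dnode.parent_node is not None:
            t.add_edge(node_map[id(dnode.parent_node)], node_map[id(dnode)],
                       dnode.edge.length)
    # unroot: drop unlabelled dangling nodes (redundant outer parentheses)
    # and suppress the degree-2 seed node a rooted newick leaves behind
    changed = True
    while changed:
        changed = False
        for node in list(t._adj):
            if not t.is_leaf(node) and t.degree(node) <= 1:
                t.remove_node(node)
                changed = True
    t.suppress_degree_two()
    return t


def parse_newick_list(text: str) -> List[Tree]:
    """Parse a multi-newick string/file content: one tree per ';'."""
    out = []
    for chunk in text.split(";"):
        if chunk.strip():
            out.append(parse_newick(chunk + ";"))
    return out


def read_tree_file(path: str) -> List[Tree]:
    with open(path) as fh:
        return parse_newick_list(fh.read())


def write_tree_file(path: str, trees: Iterable[Tree], lengths: bool = True) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick(lengths=lengths) + "\n")


# ------------------------------------------------------------------- builders


def star(labels: Iterable[str]) -> Tree:
    t = Tree()
    center = t.add_node()
    for lab in sorted(labels):
        t.add_edge(center, t.add_node(lab))
    return t


def tree_from_bipartitions(labels: Iterable[str],
                           bipartitions: Iterable[Bipartition]) -> Tree:
    """Build the unique most-resolved tree displaying a compatible set of
    bipartitions (given in the canonical no-smallest-leaf representation).

    The bipartitions must be pairwise compatible, i.e. their canonical sides
    form a laminar family; otherwise a :class:`TreeError` is raised.
    """
    labels = sorted(set(labels))
    full = frozenset(labels)
    ref = labels[0]
    clusters: List[FrozenSet[str]] = []
    for bp in set(bipartitions):
        side = frozenset(bp)
        if ref in side:
            side = full - side
        if not side or not (full - side):
            raise TreeError("trivial bipartition")
        if not side <= full:
            raise TreeError("bipartition not on the given leaf set")
        clusters.append(side)
    # laminar check
    for c1, c2 in itertools.combinations(clusters, 2):
        inter = c1 & c2
        if inter and not (c1 <= c2 or c2 <= c1):
            raise TreeError("incompatible bipartitions")

    clusters.sort(key=lambda c: (-len(c), sorted(c)))
    t = Tree()
    root = t.add_node()
    cluster_node: List[int] = []
    for i, c in enumerate(clusters):
        parent = root
        for j in range(i - 1, -1, -1):
            if c <= clusters[j]:
                parent = cluster_node[j]
                break
        node = t.add_node()
        t.add_edge(parent, node)
        cluster_node.append(node)
    for lab in labels:
        parent = root
        for j in range(len(clusters) - 1, -1, -1):
            if lab in clusters[j]:
                parent = cluster_node[j]
                break
        t.add_edge(parent, t.add_node(lab))
    t.suppress_degree_two()
    return t


# ----------------------------------------------------------------- comparison


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance (symmetric difference of non-trivial
    bipartitions); trees must share a leaf set."""
    if t1.leaf_set != t2.leaf_set:
        raise TreeError("leaf sets differ")
    return len(t1.bipartitions() ^ t2.bipartitions())


def fn_rate(true_tree: Tree, estimated_tree: Tree) -> float:
    """False-negative rate: fraction of the binary true tree's internal
    bipartitions absent from the estimate.  Equals normalized RF when the
    estimate is also binary."""
    if true_tree.leaf_set != estimated_tree.leaf_set:
        raise TreeError("leaf sets differ")
    n = true_tree.n_leaves
    if n < 4:
        return 0.0
    true_bips = true_tree.bipartitions()
    if len(true_bips) != n - 3:
        raise TreeError("true tree must be binary (n-3 internal edges)")
    missing = true_bips - estimated_tree.bipartitions()
    return len(missing) / (n - 3)


def quartet_vote(gene_trees: List[Tree]) -> Tree:
    """Resolve a 4-taxon input by plurality over induced quartet topologies."""
    votes: Counter = Counter()
    taxa = sorted(set().union(*(t.leaf_set for t in gene_trees)))
    if len(taxa) != 4:
        raise TreeError("quartet vote needs exactly 4 taxa")
    for t in gene_trees:
        if t.leaf_set != frozenset(taxa):
            continue
        for bp in t.bipartitions():
            votes[bp] += 1
    if not votes:
        return star(taxa)
    best = min(votes, key=lambda bp: (-votes[bp], sorted(bp)))
    return tree_from_bipartitions(taxa, [best])
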