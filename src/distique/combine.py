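"""Combining per-anchor results: distance-sum averaging and tree-sum
supertrees.

Distance-sum (the default) averages the double-anchored matrices entrywise,
skipping missing entries.  Tree-sum instead infers one tree per anchored
matrix and merges them with a compatibility supertree after discarding
outlier trees (RF distance to an initial supertree at least two standard
deviations above the mean).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .distances import DistanceMatrix
from .trees import Tree, TreeError, star


class InsufficientCoverageError(ValueError):
    """A leaf pair has no distance estimate from any anchored matrix."""


def distance_sum(matrices: Sequence[DistanceMatrix],
                 labels: Optional[Sequence[str]] = None,
                 require_complete: bool = True) -> DistanceMatrix:
    """Entrywise mean of the non-missing entries across anchored matrices.

    ``labels`` defaults to the sorted union of the inputs' labels.  With
    ``require_complete`` (the default) a pair missing from every matrix
    raises :class:`InsufficientCoverageError`; otherwise it stays missing.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    if labels is None:
        labels = sorted(set(itertools.chain.from_iterable(
            m.labels for m in matrices)))
    labels = list(labels)
    n = len(labels)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    idx = {lab: i for i, lab in enumerate(labels)}
    for m in matrices:
        for a, b in itertools.combinations(m.labels, 2):
            val = m[a, b]
            if not math.isnan(val):
                i, j = idx[a], idx[b]
                sums[i, j] += val
                counts[i, j] += 1
    data = np.full((n, n), np.nan)
    np.fill_diagonal(data, 0.0)
    for i, j in itertools.combinations(range(n), 2):
        if counts[i, j] > 0:
            data[i, j] = data[j, i] = sums[i, j] / counts[i, j]
        elif require_complete:
            raise InsufficientCoverageError(
                f"no anchored matrix covers the pair ({labels[i]}, {labels[j]}): "
                "insufficient anchor coverage — increase rounds")
    return DistanceMatrix(labels, data)


def rf_to_reference(tree: Tree, reference: Tree) -> int:
    """RF distance between a tree and the reference restricted to the tree's
    leaves."""
    if tree.leaf_set == reference.leaf_set:
        ref = reference
    else:
        ref = reference.restrict(tree.leaf_set)
    return len(tree.bipartitions() ^ ref.bipartitions())


def filter_outliers(trees: Sequence[Tree], reference: Tree) -> List[Tree]:
    """Drop trees whose RF distance to the reference is at least two
    population standard deviations above the mean.  One pass only; when the
    distances do not vary, nothing is dropped."""
    ds = np.array([rf_to_reference(t, reference) for t in trees], dtype=float)
    sd = float(ds.std())  # population SD
    if sd == 0.0:
        return list(trees)
    threshold = float(ds.mean()) + 2.0 * sd
    return [t for t, d in zip(trees, ds) if d < threshold]


# ------------------------------------------------------------------- tree-sum

PartialSplit = Tuple[FrozenSet[str], FrozenSet[str]]


def _canonical_split(side: FrozenSet[str], other: FrozenSet[str]) -> PartialSplit:
    a, b = sorted((side, other), key=lambda s: (len(s), sorted(s)))
    return (a, b)


def _split_displayed(tree: Tree, A: FrozenSet[str], B: FrozenSet[str]) -> bool:
    full = tree.leaf_set
    for side in tree.bipartitions():
        other = full - side
        if (A <= side and B <= other) or (A <= other and B <= side):
            return True
    return False


def _try_insert_split(tree: Tree, A: FrozenSet[str], B: FrozenSet[str]) -> bool:
    """Refine the tree in place so that it displays the partial split A|B,
    if some node admits it; returns whether the tree now displays the split.

    At an admitting node, clusters touching only A move behind one new node
    and clusters touching only B behind another; clusters touching neither
    stay on the middle node so that later splits can still place them on
    either side.
    """
    if _split_displayed(tree, A, B):
        return True
    for z in tree.nodes:
        if tree.is_leaf(z):
            continue
        a_cl: List[int] = []
        b_cl: List[int] = []
        n_cl: List[int] = []
        mixed = False
        for w in tree.neighbors(z):
            members = tree.leaves_behind(z, w)
            in_a, in_b = bool(members & A), bool(members & B)
            if in_a and in_b:
                mixed = True
                break
            (a_cl if in_a else b_cl if in_b else n_cl).append(w)
        if mixed or len(a_cl) < 2 or len(b_cl) < 2:
            continue
        if n_cl:
            za = tree.add_node()
            zb = tree.add_node()
            for w in a_cl:
                length = tree.edge_length(z, w)
                tree.remove_edge(z, w)
                tree.add_edge(za, w, length)
            for w in b_cl:
                length = tree.edge_length(z, w)
                tree.remove_edge(z, w)
                tree.add_edge(zb, w, length)
            tree.add_edge(za, z)
            tree.add_edge(z, zb)
        else:
            zn = tree.add_node()
            for w in a_cl:
                length = tree.edge_length(z, w)
                tree.remove_edge(z, w)
                tree.add_edge(zn, w, length)
            tree.add_edge(zn, z)
        return True
    return False


def _display_support(trees: Sequence[Tree], A: FrozenSet[str],
                     B: FrozenSet[str]) -> int:
    """Number of input trees displaying the partial split once restricted to
    their own leaves (restrictions leaving fewer than 2 leaves on a side
    carry no evidence)."""
    support = 0
    for t in trees:
        Ar, Br = A & t.leaf_set, B & t.leaf_set
        if len(Ar) < 2 or len(Br) < 2:
            continue
        if _split_displayed(t, Ar, Br):
            support += 1
    return support


def _greedy_split_insertion(trees: Sequence[Tree],
                            labels: Sequence[str]) -> Tree:
    """Heuristic fallback for incompatible inputs: insert partial splits in
    decreasing display-support whenever some node admits them."""
    splits = set()
    for t in trees:
        full = t.leaf_set
        for side in t.bipartitions():
            splits.add(_canonical_split(side, full - side))
    weights = {sp: _display_support(trees, *sp) for sp in splits}
    ordered = sorted(
        weights,
        key=lambda sp: (-weights[sp], -len(sp[0]) - len(sp[1]),
                        sorted(sp[0]), sorted(sp[1])))
    out = star(labels)
    for A, B in ordered:
        _try_insert_split(out, A, B)
    return out


def _attach_leaf(tree: Tree, edge: Tuple[int, int], label: str) -> Tree:
    t = tree.copy()
    a, b = edge
    t.remove_edge(a, b)
    mid = t.add_node()
    t.add_edge(a, mid)
    t.add_edge(mid, b)
    t.add_edge(mid, t.add_node(label))
    return t


def displays(supertree: Tree, subtree: Tree) -> bool:
    """Whether the supertree displays every non-trivial bipartition of the
    subtree (after restriction to the subtree's leaves)."""
    shared = supertree.leaf_set & subtree.leaf_set
    if len(shared) < 4:
        return True
    sub = subtree if subtree.leaf_set == shared else subtree.restrict(shared)
    sup = supertree if supertree.leaf_set == shared else supertree.restrict(shared)
    return sub.bipartitions() <= sup.bipartitions()


def _dfs_supertree(trees: Sequence[Tree], labels: Sequence[str],
                   search_budget: int = 50000) -> Optional[Tree]:
    """Exact supertree for mutually compatible inputs.

    The largest input is the scaffold; the remaining labels are attached one
    edge at a time by depth-first search, pruning any placement that stops
    some input from being displayed on the leaves placed so far, and
    verifying at the end that every input is displayed.  For compatible
    inputs the true placements survive every pruning step, so a refining
    tree is always found; for incompatible inputs (or an exhausted budget)
    returns ``None``.
    """
    scaffold = max(trees, key=lambda t: t.n_leaves)
    missing = sorted(set(labels) - scaffold.leaf_set)
    budget = [search_budget]
    relevant: Dict[str, List[Tree]] = {
        x: [t for t in trees if x in t.leaf_set] for x in missing}

    def dfs(current: Tree, remaining: List[str]) -> Optional[Tree]:
        if not remaining:
            if all(displays(current, t) for t in trees):
                return current
            return None
        x, rest = remaining[0], remaining[1:]
        for edge in current.edges():
            budget[0] -= 1
            if budget[0] <= 0:
                raise _BudgetExhausted
            cand = _attach_leaf(current, edge[:2], x)
            if all(displays(cand, t) for t in relevant[x]):
                found = dfs(cand, rest)
                if found is not None:
                    return found
        return None

    try:
        return dfs(scaffold.copy(), missing)
    except _BudgetExhausted:
        return None


class _BudgetExhausted(Exception):
    pass


def _centrality_order(trees: Sequence[Tree]) -> List[int]:
    """Input indices ordered from most to least central (mean normalized RF
    on pairwise shared leaves; ties by input order)."""
    m = len(trees)
    score = [0.0] * m
    for i, j in itertools.combinations(range(m), 2):
        shared = trees[i].leaf_set & trees[j].leaf_set
        if len(shared) < 4:
            d = 0.5
        else:
            ti = trees[i].restrict(shared)
            tj = trees[j].restrict(shared)
            denom = max(1, 2 * (len(shared) - 3))
            d = len(ti.bipartitions() ^ tj.bipartitions()) / denom
        score[i] += d
        score[j] += d
    return sorted(range(m), key=lambda i: (score[i], i))


def compatibility_supertree(trees: Sequence[Tree],
                            labels: Optional[Sequence[str]] = None) -> Tree:
    """Supertree of trees on overlapping leaf subsets.

    Mutually compatible inputs yield a tree displaying every input
    bipartition (a compatibility supertree).  With incompatible inputs,
    trees are considered from most to least central and each is kept only
    if a joint supertree of the kept set still exists, so conflicting
    minority trees are ignored; if the exact search is ever exhausted a
    greedy split-insertion heuristic stands in.
    """
    if not trees:
        raise ValueError("no input trees")
    if labels is None:
        labels = sorted(set(itertools.chain.from_iterable(
            t.leaf_set for t in trees)))
    labels = list(labels)
    accepted: List[Tree] = []
    for idx in _centrality_order(trees):
        trial = accepted + [trees[idx]]
        sub_labels = sorted(set(itertools.chain.from_iterable(
            t.leaf_set for t in trial)))
        if _dfs_supertree(trial, sub_labels) is not None:
            accepted = trial
    found = _dfs_supertree(accepted, labels)
    if found is not None:
        return found
    return _greedy_split_insertion(trees, labels)


def tree_sum(trees: Sequence[Tree],
             labels: Optional[Sequence[str]] = None) -> Tree:
    """Combine anchored trees: initial greedy supertree, one RF outlier
    filtering pass (two-SD rule), then the supertree is recomputed on the
    surviving trees."""
    if len(trees) < 2:
        raise ValueError("tree-sum needs at least 2 input trees")
    initial = compatibility_supertree(trees, labels)
    kept = filter_outliers(trees, initial)
    return compatibility_supertree(kept, labels)
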