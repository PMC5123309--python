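"""Smoothed empirical anchored quartet frequencies.

For a fixed anchor pair (u, v), each gene tree votes on every other leaf
pair (a, b): the induced quartet on {a, b, u, v} either shows ab.uv
(concordant with the anchors being sisters), one of the two alternatives, or
is unresolved/missing.  Counts are smoothed with the Krichevsky-Trofimov
add-half estimator, (c + 0.5) / (k + 1.5), which keeps every frequency
strictly inside (0, 1) so that -ln p is always finite.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

from .trees import Tree, TreeError


class FrequencyTable:
    """Per-pair concordant counts and smoothed frequencies for one anchor
    pair.

    For a leaf pair (a, b): ``c`` counts gene trees whose induced quartet on
    {a, b, u, v} is ab.uv, and ``k`` counts gene trees in which that quartet
    is present and resolved (the per-pair effective sample size; trees
    missing a taxon of the quartet or unresolved on it count for neither).
    """

    def __init__(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError("anchors must be distinct")
        self.u, self.v = min(u, v), max(u, v)
        self._counts: Dict[Tuple[str, str], List[int]] = {}
        self.labels: Set[str] = set()
        self.n_trees_used = 0

    @staticmethod
    def _key(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def _bump(self, a: str, b: str, concordant: bool) -> None:
        cell = self._counts.setdefault(self._key(a, b), [0, 0])
        cell[1] += 1
        if concordant:
            cell[0] += 1

    def counts(self, a: str, b: str) -> Tuple[int, int]:
        """(concordant count c, effective sample size k) for the pair."""
        c, k = self._counts.get(self._key(a, b), (0, 0))
        return c, k

    def k_eff(self, a: str, b: str) -> int:
        return self.counts(a, b)[1]

    def p_hat(self, a: str, b: str) -> float:
        """KT-smoothed frequency (c + 0.5) / (k + 1.5), strictly in (0, 1);
        equals the uniform prior 1/3 when the pair was never observed."""
        c, k = self.counts(a, b)
        return (c + 0.5) / (k + 1.5)

    def pairs(self) -> List[Tuple[str, str]]:
        return sorted(itertools.combinations(sorted(self.labels), 2))

    def to_tsv(self) -> str:
        lines = ["a\tb\tcount\tk_eff\tp_hat"]
        for a, b in self.pairs():
            c, k = self.counts(a, b)
            lines.append(f"{a}\t{b}\t{c}\t{k}\t{self.p_hat(a, b):.6f}")
        return "\n".join(lines) + "\n"


def anchored_frequencies(gene_trees: Iterable[Tree], u: str, v: str) -> FrequencyTable:
    """Tally anchored quartet frequencies over a gene-tree collection.

    Cost is Theta(n^2) per gene tree: one linear path-attachment pass gives
    each leaf a token, and the quartet on {a, b, u, v} is ab.uv exactly when
    the tokens of a and b agree.  Gene trees missing u or v contribute
    nothing; raises if no gene tree contains both anchors.
    """
    if u == v:
        raise ValueError("anchors must be distinct")
    table = FrequencyTable(u, v)
    for tree in gene_trees:
        present = tree.leaf_set
        table.labels.update(present - {u, v})
        if u not in present or v not in present:
            continue
        table.n_trees_used += 1
        tokens = tree.path_attachment(u, v)
        others = sorted(tokens)
        for a, b in itertools.combinations(others, 2):
            ta, tb = tokens[a], tokens[b]
            if ta == tb:
                table._bump(a, b, True)
            elif ta[0] == tb[0]:
                # same path vertex, different off-path edge: a polytomy
                # leaves the quartet unresolved — excluded from c and k
                continue
            else:
                table._bump(a, b, False)
    if table.n_trees_used == 0:
        raise ValueError(f"anchor pair ({u}, {v}) unusable: "
                         "no gene tree contains both anchors")
    return table


def cluster_frequency(table: FrequencyTable, A: Iterable[str], B: Iterable[str]) -> float:
    """Cluster-averaged anchored frequency p_bar(uv.AB): the arithmetic mean
    of p_hat(a, b) over a in A, b in B.  Pairs never observed contribute the
    prior value 1/3.  A and B must be disjoint, non-empty, and avoid the
    anchors."""
    A, B = sorted(set(A)), sorted(set(B))
    if not A or not B:
        raise ValueError("clusters must be non-empty")
    if set(A) & set(B):
        raise ValueError("clusters overlap")
    if {table.u, table.v} & (set(A) | set(B)):
        raise ValueError("clusters must not contain the anchors")
    total = 0.0
    for a in A:
        for b in B:
            total += table.p_hat(a, b)
    return total / (len(A) * len(B))


def cluster_informative_pairs(table: FrequencyTable,
                              A: Iterable[str], B: Iterable[str]) -> int:
    """Number of (a, b) pairs across the two clusters with k_eff > 0; zero
    means the cluster average carries no signal and should be treated as a
    missing distance."""
    return sum(1 for a in set(A) for b in set(B) if table.k_eff(a, b) > 0)
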