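"""Anchored additive distance transforms.

The central fact exploited here: fix two "anchor" leaves (u, v) of a tree T.
For every other pair (a, b), look at the induced quartet {a, b, u, v} — its
topology and its internal branch length tau.  Any transform of the form

    D'_uv[a, b] = beta + alpha * tau     if ab.uv is NOT the quartet topology
    D'_uv[a, b] = beta - f(tau)          if ab.uv IS the quartet topology

with alpha, beta > 0 and f monotonically increasing with 0 < f(x) < beta,
yields a matrix that is additive and corresponds to the topology of T
restricted to the non-anchor leaves — even though the individual entries are
"wrong" as distances.  Summing over one or both anchors (single anchored,
all-pairs anchored) preserves this, and a max-variant recovers the internal
path lengths of T exactly.

Under the multi-species coalescent the transform with beta = ln 3, alpha = 1
and f(x) = ln(3 - 2 e^-x) coincides with -ln p(ab.uv), the negative log of
the probability that gene trees display ab.uv; the same machinery therefore
turns empirical quartet frequencies into distances for species-tree
estimation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .frequencies import FrequencyTable, anchored_frequencies
from .trees import Tree


class NotAdditiveError(ValueError):
    """The four-point condition fails on some quartet."""


class UnresolvedQuartetError(ValueError):
    """All three pair-sums equal: star quartet (zero internal branch)."""


# --------------------------------------------------------------- DistanceMatrix


class DistanceMatrix:
    """Symmetric labelled distance matrix; ``nan`` marks a missing entry."""

    def __init__(self, labels: Sequence[str],
                 data: Optional[np.ndarray] = None) -> None:
        self.labels: Tuple[str, ...] = tuple(labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        n = len(self.labels)
        self._idx = {lab: i for i, lab in enumerate(self.labels)}
        if data is None:
            self.data = np.full((n, n), np.nan)
            np.fill_diagonal(self.data, 0.0)
        else:
            data = np.asarray(data, dtype=float)
            if data.shape != (n, n):
                raise ValueError("shape mismatch")
            self.data = data.copy()

    # -- access

    def index(self, label: str) -> int:
        return self._idx[label]

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        a, b = pair
        return float(self.data[self._idx[a], self._idx[b]])

    def set(self, a: str, b: str, value: float) -> None:
        i, j = self._idx[a], self._idx[b]
        self.data[i, j] = value
        self.data[j, i] = value

    def is_missing(self, a: str, b: str) -> bool:
        return bool(np.isnan(self.data[self._idx[a], self._idx[b]]))

    @property
    def has_missing(self) -> bool:
        off = ~np.eye(len(self.labels), dtype=bool)
        return bool(np.isnan(self.data[off]).any())

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(self.labels, self.data)

    def restrict(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self._idx[lab] for lab in labels]
        return DistanceMatrix(labels, self.data[np.ix_(idx, idx)])

    # -- I/O

    def to_phylip(self) -> str:
        """Square PHYLIP distance format (missing entries written as -1)."""
        lines = [f"    {len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            row = " ".join(
                "-1" if np.isnan(x) else f"{x:.10f}" for x in self.data[i]
            )
            lines.append(f"{lab}  {row}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tree(cls, tree: Tree) -> "DistanceMatrix":
        """Additive matrix of leaf-to-leaf path lengths of an edge-weighted
        tree (all branch lengths required)."""
        return cls(tree.leaves, _path_length_matrix(tree, internal_only=False))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DistanceMatrix n={len(self.labels)}>"


def _path_length_matrix(tree: Tree, internal_only: bool) -> np.ndarray:
    labels = tree.leaves
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    for lab in labels:
        src = tree.node_of(lab)
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for w in tree._adj[x]:
                if w in dist:
                    continue
                ln = tree.edge_length(x, w)
                if internal_only:
                    step = 0.0 if (tree.is_leaf(x) or tree.is_leaf(w)) else ln
                else:
                    step = ln
                if step is None:
                    raise ValueError("tree is missing branch lengths")
                dist[w] = dist[x] + step
                stack.append(w)
        for other, node in ((l, tree.node_of(l)) for l in labels):
            out[idx[lab], idx[other]] = dist[node]
    np.fill_diagonal(out, 0.0)
    return out


def internal_path_length_matrix(tree: Tree) -> DistanceMatrix:
    """Sum of *internal* branch lengths along each leaf-to-leaf path
    (0 for sister pairs) — the quantity the max-anchored transform recovers."""
    return DistanceMatrix(tree.leaves, _path_length_matrix(tree, internal_only=True))


# ---------------------------------------------------------------- TransformSpec


@dataclass(frozen=True)
class TransformSpec:
    """A valid anchored-distance transform (alpha, beta, f).

    Requirements: alpha > 0, beta > 0, f monotonically increasing with
    0 < f(x) < beta for all x > 0.
    """

    alpha: float
    beta: float
    f: Callable[[float], float]

    def validate(self, grid: Optional[Sequence[float]] = None) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if grid is None:
            grid = np.geomspace(1e-3, 10.0, 50)
        prev = 0.0
        for x in grid:
            fx = self.f(float(x))
            if not (0.0 < fx < self.beta):
                raise ValueError(f"f({x}) = {fx} outside (0, beta)")
            if fx <= prev:
                raise ValueError("f is not increasing on the test grid")
            prev = fx

    def entry(self, sister: bool, tau: float) -> float:
        """Anchored entry for one quartet: ``sister`` means ab.uv is the
        quartet topology (the anchors are sisters, paired against a, b)."""
        if tau <= 0:
            raise ValueError("quartet internal branch length must be positive")
        if sister:
            return self.beta - self.f(tau)
        return self.beta + self.alpha * tau


def msc_transform() -> TransformSpec:
    """The coalescent instantiation: beta = ln 3, alpha = 1,
    f(x) = ln(3 - 2 e^-x), so that entries equal -ln p(ab.uv)."""
    return TransformSpec(alpha=1.0, beta=math.log(3.0),
                         f=lambda x: math.log(3.0 - 2.0 * math.exp(-x)))


MSC_TRANSFORM = msc_transform()


# --------------------------------------------------------------- quartet calls


def quartet_topology_and_length(
    D: DistanceMatrix, quartet: Sequence[str], tol: float = 1e-8
) -> Tuple[Tuple[Tuple[str, str], Tuple[str, str]], float]:
    """Infer the quartet topology and internal branch length from distances.

    Of the three pair-sums of {a,b,c,d}, the strictly smallest identifies the
    sister pairing and tau = (median - min) / 2.  Raises
    :class:`UnresolvedQuartetError` when all three sums coincide and
    :class:`NotAdditiveError` when the two larger sums disagree beyond
    ``tol`` (relative).
    """
    a, b, c, d = quartet
    sums = [
        (D[a, b] + D[c, d], ((a, b), (c, d))),
        (D[a, c] + D[b, d], ((a, c), (b, d))),
        (D[a, d] + D[b, c], ((a, d), (b, c))),
    ]
    sums.sort(key=lambda t: t[0])
    s_min, s_med, s_max = sums[0][0], sums[1][0], sums[2][0]
    scale = max(1.0, abs(s_min), abs(s_max))
    if s_max - s_min <= tol * scale:
        raise UnresolvedQuartetError(f"star quartet {quartet}")
    if s_max - s_med > tol * scale:
        raise NotAdditiveError(
            f"four-point condition fails on {quartet}: sums {s_min}, {s_med}, {s_max}"
        )
    if s_med - s_min <= tol * scale:
        raise UnresolvedQuartetError(f"ambiguous quartet {quartet}")
    tau = 0.5 * (s_med - s_min)
    return sums[0][1], tau


def anchored_entry(sister: bool, tau: float, spec: TransformSpec) -> float:
    """Single transformed entry; see :meth:`TransformSpec.entry`."""
    return spec.entry(sister, tau)


def _quartet_entry(D: DistanceMatrix, a: str, b: str, u: str, v: str,
                   spec: TransformSpec, tol: float) -> float:
    topo, tau = quartet_topology_and_length(D, (a, b, u, v), tol=tol)
    sister = frozenset(topo[0]) == frozenset((a, b))
    return spec.entry(sister, tau)


def double_anchored_from_matrix(
    D: DistanceMatrix, u: str, v: str, spec: TransformSpec, tol: float = 1e-8
) -> DistanceMatrix:
    """Double anchored matrix on the leaf set minus {u, v}: additive, and its
    tree equals the input tree restricted to the non-anchor leaves."""
    if len(D.labels) < 6:
        raise ValueError("need at least 6 leaves to double-anchor")
    rest = [lab for lab in D.labels if lab not in (u, v)]
    out = DistanceMatrix(rest)
    for a, b in itertools.combinations(rest, 2):
        out.set(a, b, _quartet_entry(D, a, b, u, v, spec, tol))
    return out


def single_anchored(
    D: DistanceMatrix, v: str, spec: TransformSpec, tol: float = 1e-8
) -> DistanceMatrix:
    """Sum of double anchored entries over the second anchor u."""
    rest = [lab for lab in D.labels if lab != v]
    out = DistanceMatrix(rest)
    for a, b in itertools.combinations(rest, 2):
        total = 0.0
        for u in rest:
            if u in (a, b):
                continue
            total += _quartet_entry(D, a, b, u, v, spec, tol)
        out.set(a, b, total)
    return out


def all_pairs_anchored(
    D: DistanceMatrix, spec: TransformSpec, tol: float = 1e-8
) -> DistanceMatrix:
    """Sum over all ordered anchor pairs (v, u); each unordered pair
    contributes twice.  Additive for the full input topology."""
    out = DistanceMatrix(D.labels)
    for a, b in itertools.combinations(D.labels, 2):
        rest = [lab for lab in D.labels if lab not in (a, b)]
        total = 0.0
        for u, v in itertools.combinations(rest, 2):
            total += 2.0 * _quartet_entry(D, a, b, u, v, spec, tol)
        out.set(a, b, total)
    return out


def all_pairs_max(
    D: DistanceMatrix, spec: TransformSpec, tol: float = 1e-8
) -> DistanceMatrix:
    """Max-anchored matrix: entry [a,b] is the largest
    max(0, (D'_uv[a,b] - beta) / alpha) over anchor pairs, which equals the
    sum of internal branch lengths on the a--b path (0 for sisters)."""
    out = DistanceMatrix(D.labels)
    for a, b in itertools.combinations(D.labels, 2):
        rest = [lab for lab in D.labels if lab not in (a, b)]
        best = 0.0
        for u, v in itertools.combinations(rest, 2):
            e = _quartet_entry(D, a, b, u, v, spec, tol)
            best = max(best, (e - spec.beta) / spec.alpha)
        out.set(a, b, max(0.0, best))
    return out


# ------------------------------------------------------------ MSC (empirical)


def msc_double_anchored(table: FrequencyTable) -> DistanceMatrix:
    """Empirical double anchored matrix: entry [a,b] = -ln p_hat(ab.uv).
    Smoothing keeps every present entry finite; pairs never observed with
    both anchors are marked missing."""
    labels = sorted(table.labels)
    out = DistanceMatrix(labels)
    for a, b in itertools.combinations(labels, 2):
        if table.k_eff(a, b) == 0:
            continue
        out.set(a, b, -math.log(table.p_hat(a, b)))
    return out


def msc_all_pairs(gene_trees: List[Tree],
                  labels: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Empirical all-pairs anchored matrix (ordered anchor-pair sum of
    -ln p_hat over every anchor pair avoiding {a, b}).  Theta(n^4 k).

    Missing contributions (pair never observed with an anchor pair) are
    skipped; an entry is missing only if every contribution is missing.
    """
    if labels is None:
        labels = sorted(set().union(*(t.leaf_set for t in gene_trees)))
    labels = list(labels)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=int)
    for u, v in itertools.combinations(labels, 2):
        table = anchored_frequencies(gene_trees, u, v)
        for a, b in itertools.combinations(sorted(table.labels), 2):
            if table.k_eff(a, b) == 0:
                continue
            i, j = idx[a], idx[b]
            acc[i, j] += -math.log(table.p_hat(a, b))
            cnt[i, j] += 1
    data = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        if cnt[i, j] > 0:
            data[i, j] = data[j, i] = 2.0 * acc[i, j]  # ordered pairs: x2
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(labels, data)


# ------------------------------------------------------------------ additivity


def is_additive(D: DistanceMatrix, tol: float = 1e-8) -> bool:
    """Four-point condition on every 4-subset: the two largest pair-sums must
    agree within ``tol`` (relative)."""
    if D.has_missing:
        raise ValueError("matrix has missing entries")
    labels = D.labels
    for quartet in itertools.combinations(labels, 4):
        a, b, c, d = quartet
        sums = sorted((
            D[a, b] + D[c, d],
            D[a, c] + D[b, d],
            D[a, d] + D[b, c],
        ))
        scale = max(1.0, abs(sums[0]), abs(sums[2]))
        if sums[2] - sums[1] > tol * scale:
            return False
    return True
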