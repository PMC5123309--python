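"""Classic neighbor joining with deterministic tie-breaking.

NJ recovers the exact topology from any additive matrix and has an l-infinity
safety radius of half the minimum internal branch length, which is what makes
it a valid back end for anchored distance matrices.  Branch lengths on the
output are the usual NJ estimates; on anchored matrices they are not
interpretable (the transforms preserve topology, not path lengths).
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional

import numpy as np

from .distances import DistanceMatrix
from .trees import Tree

#: Signature for an external distance-method hook: takes a complete
#: DistanceMatrix, returns an unrooted Tree on the same labels.
DistanceEngine = Callable[[DistanceMatrix], Tree]


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining, O(n^3).

    Labels are processed in sorted order and Q-criterion ties are broken by
    the lexicographically smallest index pair, so the result is invariant
    under input label permutation and deterministic.  Raises on missing
    entries (combine anchored matrices first).
    """
    if D.has_missing:
        raise ValueError("distance matrix has missing entries; combine first")
    order = sorted(D.labels)
    n = len(order)
    if n < 2:
        raise ValueError("need at least 2 labels")

    tree = Tree()
    if n == 2:
        a, b = (tree.add_node(l) for l in order)
        tree.add_edge(a, b, D[order[0], order[1]])
        return tree

    d = D.restrict(order).data.copy()
    nodes: List[int] = [tree.add_node(lab) for lab in order]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                if q < best_q:
                    best_q = q
                    best = (i, j)
        i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        new = tree.add_node()
        tree.add_edge(nodes[ai], new, max(0.0, vi))
        tree.add_edge(nodes[aj], new, max(0.0, vj))
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for t_idx, at in enumerate(active):
            if at in (ai, aj):
                continue
            new_row[at] = 0.5 * (d[ai, at] + d[aj, at] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [d.shape[0] - 1]
        # re-point the appended index at the fresh row
        nodes_idx = d.shape[0] - 1
        if nodes_idx >= len(nodes):  # pragma: no cover - invariant guard
            raise RuntimeError("index bookkeeping error")

    # final 3 (or fewer) taxa join at one hub
    if len(active) == 3:
        x, y, z = active
        hub = tree.add_node()
        tree.add_edge(nodes[x], hub,
                      max(0.0, 0.5 * (d[x, y] + d[x, z] - d[y, z])))
        tree.add_edge(nodes[y], hub,
                      max(0.0, 0.5 * (d[x, y] + d[y, z] - d[x, z])))
        tree.add_edge(nodes[z], hub,
                      max(0.0, 0.5 * (d[x, z] + d[y, z] - d[x, y])))
    else:  # pragma: no cover - unreachable for n >= 3
        a, b = active
        tree.add_edge(nodes[a], nodes[b], d[a, b])
    return tree
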