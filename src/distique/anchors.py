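"""Targeted sampling of anchor pairs over consensus polytomies.

Each round, the clusters of every polytomy are randomly matched into pairs
(ceil(d/2) pairs; an odd leftover cluster is re-paired with a random matched
one) and one species is drawn per cluster per pair.  Degree-4 and degree-5
polytomies cannot be resolved by a double-anchored matrix (too few clusters
remain), so for them every C(4,2) or C(5,2) cluster pair is used.  Each
sampled anchor pair is then assigned to resolve every polytomy on the path
between its two species in the consensus tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .consensus import PolytomyContext
from .trees import Tree


@dataclass(frozen=True)
class AnchorPair:
    """One sampled anchor pair and, after target assignment, the polytomies
    it resolves.  ``targets`` holds (context index, cluster-of-u label,
    cluster-of-v label) triples."""

    u: str
    v: str
    round: int
    context_index: int
    cluster_u: str
    cluster_v: str
    targets: Tuple[Tuple[int, str, str], ...] = ()


@dataclass
class AnchorPlan:
    pairs: List[AnchorPair]
    rounds: int
    seed: int

    def to_tsv(self) -> str:
        lines = ["round\tu\tv\ttarget_polytomy\tcluster_u\tcluster_v"]
        for p in self.pairs:
            for ci, cu, cv in p.targets:
                lines.append(f"{p.round}\t{p.u}\t{p.v}\t{ci}\t{cu}\t{cv}")
        return "\n".join(lines) + "\n"


def _rng_for(seed: int, round_idx: int, context_idx: int) -> np.random.Generator:
    # per-polytomy substream: adding a polytomy does not perturb others
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(round_idx, context_idx)))


def _draw_species(rng: np.random.Generator, members: Sequence[str]) -> str:
    members = sorted(members)
    return members[int(rng.integers(len(members)))]


def sample_anchor_pairs(contexts: Sequence[PolytomyContext], rounds: int,
                        seed: int, all_pairs: bool = False) -> AnchorPlan:
    """Sample anchor pairs for every polytomy over the given rounds.

    With ``all_pairs`` every C(d,2) cluster pair is used for every polytomy
    (the exhaustive variants); otherwise a random perfect matching per
    polytomy per round, with the degree-4/5 all-pairs special case.
    Species are re-drawn per pair each round.  Deterministic given the seed.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not contexts:
        raise ValueError("no polytomy contexts")
    pairs: List[AnchorPair] = []
    for r in range(rounds):
        for ci, ctx in enumerate(contexts):
            rng = _rng_for(seed, r, ci)
            labels = sorted(ctx.clusters)
            d = len(labels)
            if all_pairs or d <= 5:
                cluster_pairs = list(itertools.combinations(labels, 2))
            else:
                perm = [labels[i] for i in rng.permutation(d)]
                cluster_pairs = [(perm[2 * i], perm[2 * i + 1])
                                 for i in range(d // 2)]
                if d % 2:
                    leftover = perm[-1]
                    partner = perm[int(rng.integers(d - 1))]
                    cluster_pairs.append((leftover, partner))
            for cu, cv in cluster_pairs:
                u = _draw_species(rng, ctx.clusters[cu])
                v = _draw_species(rng, ctx.clusters[cv])
                pairs.append(AnchorPair(u=u, v=v, round=r, context_index=ci,
                                        cluster_u=cu, cluster_v=cv))
    return AnchorPlan(pairs=pairs, rounds=rounds, seed=seed)


def assign_targets(plan: AnchorPlan, consensus: Tree,
                   contexts: Sequence[PolytomyContext]) -> AnchorPlan:
    """Assign each anchor pair to every polytomy on its consensus path.

    For each targeted polytomy the two anchors necessarily lie in distinct
    clusters (the path enters and leaves through different pendant edges);
    those cluster roles are recorded with the target.
    """
    node_to_ci = {ctx.node: i for i, ctx in enumerate(contexts)}
    new_pairs: List[AnchorPair] = []
    for pair in plan.pairs:
        path = consensus.node_path(consensus.node_of(pair.u),
                                   consensus.node_of(pair.v))
        edge_lookup = [
            {nbr: lab for lab, nbr in contexts[node_to_ci[node]].edge_nodes.items()}
            if node in node_to_ci else None
            for node in path
        ]
        targets: List[Tuple[int, str, str]] = []
        for i, node in enumerate(path):
            if edge_lookup[i] is None:
                continue
            cu = edge_lookup[i][path[i - 1]]
            cv = edge_lookup[i][path[i + 1]]
            targets.append((node_to_ci[node], cu, cv))
        new_pairs.append(replace(pair, targets=tuple(targets)))
    return AnchorPlan(pairs=new_pairs, rounds=plan.rounds, seed=plan.seed)
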