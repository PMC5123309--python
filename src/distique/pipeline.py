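"""End-to-end species-tree estimation pipeline.

Stages: (1) strict-majority consensus of the gene trees (optional); (2) one
context per consensus polytomy; (3) anchor-pair sampling over the polytomies
(with the degree-4/5 all-pairs special case), each pair targeting every
polytomy on its consensus path; (4) per anchor pair, smoothed anchored
quartet frequencies, cluster-averaged per polytomy and turned into -ln
distances between non-anchor clusters; (5) per-polytomy combination by the
chosen method; (6) neighbor joining (or an external distance engine) on the
cluster labels; (7) grafting every resolution back into the consensus.

The output is a binary topology on all input taxa; branch lengths from the
anchored distances are not meaningful and are dropped by default.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .anchors import AnchorPair, AnchorPlan, assign_targets, sample_anchor_pairs
from .combine import InsufficientCoverageError, distance_sum, tree_sum
from .consensus import PolytomyContext, graft_resolution, majority_consensus, polytomy_contexts
from .distances import DistanceMatrix
from .frequencies import (FrequencyTable, anchored_frequencies,
                          cluster_frequency, cluster_informative_pairs)
from .nj import DistanceEngine, neighbor_joining
from .trees import Tree, TreeError, quartet_vote, star

logger = logging.getLogger("distique")

METHODS = ("distance-sum", "tree-sum", "all-pairs", "all-pairs-max")

LN3 = math.log(3.0)


@dataclass
class DistiqueResult:
    tree: Tree
    report: Dict = field(default_factory=dict)


def _strip_lengths(tree: Tree) -> Tree:
    t = tree.copy()
    for a in t._adj:
        for b in t._adj[a]:
            t._adj[a][b] = None
    return t


def _cluster_matrix(table: FrequencyTable, ctx: PolytomyContext,
                    exclude: Tuple[str, str]) -> DistanceMatrix:
    """Double-anchored matrix on the polytomy's cluster labels minus the two
    anchor clusters; entries are -ln of the cluster-averaged frequency, and
    an entry with no informative leaf pair stays missing."""
    labels = [lab for lab in sorted(ctx.clusters) if lab not in exclude]
    out = DistanceMatrix(labels)
    for A, B in itertools.combinations(labels, 2):
        if cluster_informative_pairs(table, ctx.clusters[A], ctx.clusters[B]) == 0:
            continue
        out.set(A, B, -math.log(
            cluster_frequency(table, ctx.clusters[A], ctx.clusters[B])))
    return out


def _resolve_distance_sum(matrices: List[DistanceMatrix], labels: List[str],
                          engine: Optional[DistanceEngine]) -> Tree:
    combined = distance_sum(matrices, labels=labels)
    return (engine or neighbor_joining)(combined)


def _resolve_all_pairs(matrices: List[DistanceMatrix], labels: List[str],
                       engine: Optional[DistanceEngine],
                       use_max: bool) -> Tree:
    """Exhaustive-anchor combination on cluster labels: the ordered-pair sum
    of -ln frequencies (all-pairs) or the max over anchors of the implied
    quartet length (all-pairs-max)."""
    out = DistanceMatrix(labels)
    for A, B in itertools.combinations(labels, 2):
        vals = [m[A, B] for m in matrices
                if A in m.labels and B in m.labels and not m.is_missing(A, B)]
        if not vals:
            raise InsufficientCoverageError(
                f"no anchored matrix covers the pair ({A}, {B}): "
                "insufficient anchor coverage — increase rounds")
        if use_max:
            out.set(A, B, max(0.0, max(v - LN3 for v in vals)))
        else:
            out.set(A, B, 2.0 * sum(vals))
    return (engine or neighbor_joining)(out)


def run_distique(gene_trees: Sequence[Tree], *,
                 method: str = "distance-sum",
                 rounds: int = 2,
                 use_consensus: bool = True,
                 seed: int = 0,
                 anchors: str = "sampled",
                 engine: Optional[DistanceEngine] = None,
                 keep_lengths: bool = False) -> DistiqueResult:
    """Estimate the species-tree topology from unrooted gene trees.

    Parameters mirror the CLI: ``method`` chooses how per-anchor results are
    combined per polytomy; ``rounds`` repeats the anchor sampling;
    ``use_consensus`` toggles the majority-consensus stage (when off, the
    whole leaf set forms one star polytomy); ``anchors='all'`` forces every
    cluster pair as an anchor pair.  Deterministic given the seed.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if not gene_trees:
        raise TreeError("no gene trees")

    taxa = sorted(set().union(*(t.leaf_set for t in gene_trees)))
    n = len(taxa)
    if use_consensus:
        for t in gene_trees:
            if t.leaf_set != frozenset(taxa):
                raise TreeError("gene trees must share a leaf set; "
                                "rerun with use_consensus=False for partial trees")
    report: Dict = {"n_taxa": n, "k_genes": len(gene_trees), "method": method,
                    "rounds": rounds, "use_consensus": use_consensus,
                    "seed": seed}

    if n < 4:
        raise TreeError("need at least 4 shared taxa")
    if n == 4:
        tree = quartet_vote(list(gene_trees))
        report["n_polytomies"] = 0
        return DistiqueResult(tree=tree, report=report)

    consensus = majority_consensus(list(gene_trees)) if use_consensus else star(taxa)
    contexts = polytomy_contexts(consensus)
    report["n_polytomies"] = len(contexts)
    report["polytomy_degrees"] = [c.degree for c in contexts]
    report["consensus_resolution"] = (
        len(consensus.bipartitions()) / (n - 3) if n > 3 else 1.0)
    logger.info("consensus: %d/%d internal edges, %d polytomies (degrees %s)",
                len(consensus.bipartitions()), n - 3, len(contexts),
                report["polytomy_degrees"])
    if not contexts:
        tree = consensus if keep_lengths else _strip_lengths(consensus)
        return DistiqueResult(tree=tree, report=report)

    all_pairs_flag = (anchors == "all") or method in ("all-pairs", "all-pairs-max")
    plan = sample_anchor_pairs(contexts, rounds, seed, all_pairs=all_pairs_flag)
    plan = assign_targets(plan, consensus, contexts)
    report["n_anchor_pairs"] = len(plan.pairs)
    logger.info("sampled %d anchor pairs over %d rounds", len(plan.pairs), rounds)

    # one frequency table per distinct anchor species pair
    tables: Dict[Tuple[str, str], FrequencyTable] = {}
    for pair in plan.pairs:
        key = (min(pair.u, pair.v), max(pair.u, pair.v))
        if key not in tables:
            tables[key] = anchored_frequencies(gene_trees, *key)

    # per-context anchored cluster matrices
    ctx_matrices: List[List[DistanceMatrix]] = [[] for _ in contexts]
    for pair in plan.pairs:
        key = (min(pair.u, pair.v), max(pair.u, pair.v))
        for ci, cu, cv in pair.targets:
            ctx_matrices[ci].append(
                _cluster_matrix(tables[key], contexts[ci], (cu, cv)))

    missing_entries = 0
    for mats in ctx_matrices:
        for m in mats:
            missing_entries += sum(
                1 for A, B in itertools.combinations(m.labels, 2)
                if m.is_missing(A, B))
    report["missing_matrix_entries"] = missing_entries

    tree = consensus
    for ci, ctx in enumerate(contexts):
        labels = sorted(ctx.clusters)
        mats = ctx_matrices[ci]
        if not mats:  # cannot happen: a polytomy always targets itself
            raise InsufficientCoverageError(f"polytomy {ci} received no anchors")
        if method == "distance-sum" or (method == "tree-sum" and ctx.degree <= 5):
            resolved = _resolve_distance_sum(mats, labels, engine)
        elif method in ("all-pairs", "all-pairs-max"):
            resolved = _resolve_all_pairs(mats, labels, engine,
                                          use_max=(method == "all-pairs-max"))
        else:  # tree-sum, degree >= 6
            subtrees = [(engine or neighbor_joining)(m) for m in mats
                        if not m.has_missing and len(m.labels) >= 4]
            if len(subtrees) >= 2:
                resolved = tree_sum(subtrees, labels=labels)
                if not resolved.is_binary:
                    # residual polytomies: refine with the distance-sum matrix
                    resolved = _refine_with_distances(resolved, mats, labels, engine)
            else:
                resolved = _resolve_distance_sum(mats, labels, engine)
        tree = graft_resolution(tree, ctx, resolved)

    if not keep_lengths:
        tree = _strip_lengths(tree)
    else:
        logger.warning("branch lengths on the output come from anchored "
                       "distances and are not interpretable")
    report["output_is_binary"] = tree.is_binary
    return DistiqueResult(tree=tree, report=report)


def _refine_with_distances(resolved: Tree, matrices: List[DistanceMatrix],
                           labels: List[str],
                           engine: Optional[DistanceEngine]) -> Tree:
    """Resolve residual polytomies of a supertree with the distance-sum
    matrix restricted to each polytomy's clusters."""
    combined = distance_sum(matrices, labels=labels, require_complete=False)
    out = resolved
    for ctx in polytomy_contexts(out):
        sub_labels = sorted(ctx.clusters)
        sub = DistanceMatrix(sub_labels)
        for A, B in itertools.combinations(sub_labels, 2):
            vals = [combined[a, b]
                    for a in ctx.clusters[A] for b in ctx.clusters[B]
                    if not combined.is_missing(a, b)]
            if not vals:
                raise InsufficientCoverageError(
                    f"no coverage between clusters {A} and {B}")
            sub.set(A, B, sum(vals) / len(vals))
        out = graft_resolution(out, ctx, (engine or neighbor_joining)(sub))
    return out
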