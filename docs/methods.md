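# Methods

## Model and assumptions

Gene trees are assumed to be generated independently by the multi-species
coalescent (MSC) within a binary species tree whose internal branch lengths
are measured in coalescent units (generations / effective population size),
with one sampled lineage per species and error-free gene-tree topologies.
All trees are treated as unrooted; rooted newick input is unrooted on read.
Gene-tree branch lengths are ignored by the estimator — only topologies
enter the quartet frequencies.

For a species-tree quartet with internal branch `τ > 0`, the unrooted
gene-tree quartet is concordant with probability `1 − (2/3)e^−τ` and takes
each discordant resolution with probability `(1/3)e^−τ`.

## Anchored distances

Let `D` be an additive matrix with quartet-length function `τ(Q)` and fix
anchors `(u, v)`.  A transform `(α, β, f)` with `α, β > 0` and `f`
monotonically increasing, `0 < f(x) < β` for `x > 0`, defines

* double anchored: `D'_uv[a,b] = β + α·τ` if `ab.uv` is not the quartet
  topology, `β − f(τ)` if it is;
* single anchored: the sum of `D'_uv[a,b]` over the second anchor `u`;
* all-pairs anchored: the sum over all ordered anchor pairs (each
  unordered pair counted twice, as implemented and tested);
* all-pairs max: `max_uv max(0, (D'_uv[a,b] − β)/α)`, which equals the sum
  of internal branch lengths on the `a–b` path (0 for sisters).

The first three are additive for the input topology restricted to the
non-anchor leaves; the fourth reproduces internal path lengths exactly.
These properties are exercised on 200 random trees per run by the test
suite and the acceptance script.  The MSC instantiation is `β = ln 3`,
`α = 1`, `f(x) = ln(3 − 2e^−x)`, for which the transformed entries equal
`−ln p(ab.uv)`; empirical frequencies thus plug in directly.

Non-positive quartet lengths are rejected (internal branch lengths are
assumed strictly positive).  The four-point additivity check uses a
relative tolerance, default `1e−8`, appropriate for matrices computed in
exact arithmetic; empirical matrices are never exactly additive and are
passed to neighbor joining without the check.

## Frequencies and smoothing

For anchors `(u, v)`, each gene tree is scanned once with a linear-time
path-attachment pass: every other leaf receives a token (path vertex,
off-path edge) relative to the `u–v` path, and `ab.uv` holds exactly when
the tokens of `a` and `b` agree, giving all pair counts in `Θ(n²)` per tree.
Counts are smoothed per pair with the Krichevsky–Trofimov add-half rule
`p̂ = (c + 0.5)/(k_ab + 1.5)`, where the per-pair effective sample size
`k_ab` excludes gene trees in which the quartet is missing a taxon or
unresolved (the reference setting assumes complete binary gene trees; the
exclusion rule is this package's least-biased extension).  A pair never
observed sits at the prior `1/3`; such entries carry no signal and are
treated as missing when averaging distances, while cluster averages use the
prior value.

## Pipeline

1. Strict-majority consensus (>50 %; ties at exactly one half excluded) of
   the gene trees.  The consensus is provably not positively misleading
   under the MSC, so refining it preserves consistency.  A flag disables
   this stage, turning the whole leaf set into one star polytomy.
2. Each consensus polytomy of degree `d` contributes one context whose `d`
   pendant clusters partition the leaf set; cluster labels are `@` plus the
   smallest contained leaf, which cannot collide with species names.
3. Anchor sampling per round: a random perfect matching of each polytomy's
   clusters (⌈d/2⌉ pairs; an odd leftover is re-paired with a uniformly
   chosen matched cluster), one species drawn per cluster per pair.
   Degree-4/5 polytomies use all C(d,2) cluster pairs.  Each sampled pair is
   assigned to every polytomy on the path between its species in the
   consensus.  Species are re-drawn per pair so extra rounds explore new
   representatives.  Substreams are derived per (round, polytomy) from the
   global seed, so the plan is reproducible and adding a polytomy does not
   perturb other draws.  Default rounds = 2; improvements beyond that are
   typically small, and the flag is exposed.
4. Per anchor pair and target polytomy, distances between the other
   clusters are `−ln` of cluster-averaged frequencies
   `p̄(uv.AB) = mean over a∈A, b∈B of p̂(ab.uv)`.  Distance-sum (default)
   averages these matrices entrywise, skipping missing entries and raising
   an actionable error if a cluster pair is covered by no anchor.
   Averaging is over unordered anchor pairs; neighbor joining is
   scale-invariant, so the factor-2 of the ordered-pair formulation is
   immaterial there (the all-pairs route keeps the ordered-sum scale).
   The open choice of averaging distances vs averaging frequencies before
   the `−ln` transform is resolved in favour of averaging distances
   (matching the distance-sum definition); frequency averaging would be a
   one-line variant.
5. The per-polytomy matrix goes to neighbor joining (deterministic
   lexicographic tie-breaking; exact recovery on additive input; output
   branch lengths clamped at zero and flagged non-interpretable), or to an
   external distance program through a square-PHYLIP/newick hook.
6. Tree-sum instead infers one tree per anchored matrix, removes outliers
   whose RF distance to an initial supertree is at least two population
   standard deviations above the mean (one pass; nothing is dropped when
   the distances do not vary), and recomputes a compatibility supertree.
   The supertree attaches missing leaves to a scaffold input by exhaustive
   search with display-consistency pruning, which provably refines all
   inputs whenever they are mutually compatible; with incompatible inputs
   trees are admitted in order of centrality and conflicting minority trees
   are ignored (a greedy split-insertion heuristic is the last resort).
   Degree-4/5 polytomies cannot yield per-anchor trees (fewer than four
   cluster labels remain), so they always take the distance route; residual
   supertree polytomies are refined with the distance-sum matrix so the
   output is binary.
7. Resolutions are grafted back into the consensus; pendant edges keep
   their clusters, new internal edges carry no length.  The output is a
   binary topology on all taxa, deterministic given the seed.

Four-taxon inputs are resolved by a direct plurality vote over induced
quartet topologies.

## Simulator

`random_species_tree` draws a uniform labeled binary topology (sequential
attachment to a uniformly chosen edge) with i.i.d. uniform branch lengths;
the default range (0.5, 2) coalescent units represents moderate incomplete
lineage sorting (per-branch discordance roughly 10–40 %).  Gene trees are
simulated exactly: within each species-tree branch, `j` lineages coalesce
after Exp(j(j−1)/2) waiting times with uniformly chosen pairs, and all
remaining lineages coalesce above the root.  The species tree is rooted on
an internal edge for simulation only; the distribution of unrooted
gene-tree topologies does not depend on the root placement.

The generator emulates the estimator's idealized regime: complete,
error-free, independent gene trees with one lineage per species.  It does
not model gene-tree estimation error, missing taxa, linkage between genes,
or multiple individuals — so passing tests demonstrate the statistical
behaviour of the method under the MSC, not robustness to the additional
noise sources of real data.

## Problem sizes and numerical choices

The acceptance computations use 200 random trees (6–12 leaves) for the
transform suites, 10 000 genes per τ for simulator fidelity, 40 replicates
of 8-taxon trees with branches in (0.5, 2) and a nested gene-count grid
{50, 200, 1000, 2000} for end-to-end recovery, and 20 datasets for the
distance-sum/all-pairs equivalence; these sizes keep the full run within a
few tens of seconds while leaving the binomial standard errors far below
the tested margins.  Additivity tolerance is relative 1e−8 (observed errors
are at machine precision, ~1e−15); the max-anchored identity is checked at
1e−9; the transform identity at 1e−12.  With branch lengths ≥ 0.5 the
8-taxon consensus is often fully resolved at large k, in which case the
anchoring stages are exercised only by the smaller gene counts and the
harder settings used elsewhere in the test suite.

## Known limitations

* Branch lengths of the output are meaningless by construction; the
  contract is topology only.
* The consensus stage requires a shared leaf set; inputs with missing taxa
  must disable it (anchored frequencies themselves handle missing taxa).
* The compatibility supertree's exhaustive search is exponential in the
  number of unplaced leaves in the worst case; it is budgeted and falls
  back to a heuristic, which can lose the display guarantee for
  incompatible inputs (where no guarantee is possible anyway).
* Balanced-minimum-evolution search (the strongest distance engine in the
  reference experiments) is not bundled; the external-engine hook accepts
  any program reading square PHYLIP and printing newick.
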