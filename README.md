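# distique

Quartet-based species-tree estimation from unrooted gene trees under the
multi-species coalescent (MSC), built on *anchored* additive distance
matrices.

## The problem and the idea

Individual gene genealogies disagree with the species tree because of
incomplete lineage sorting.  For any four species `{a, b, u, v}` whose
species-tree quartet has internal branch length `τ` (coalescent units), the
MSC gives the gene-tree quartet topologies the probabilities

```
P(concordant)      = 1 − (2/3) e^−τ
P(each discordant) = (1/3) e^−τ
```

so the species-tree quartet topology is always the most frequent one, and
the frequency encodes `τ`.  Fix two *anchor* leaves `(u, v)`.  For every
other pair `(a, b)` define

```
D*_uv[a, b] = −ln p̂(ab.uv)
```

where `p̂(ab.uv)` is the smoothed fraction of gene trees in which `a, b` are
separated from `u, v`.  As the number of genes `k` grows, this matrix
converges to an *additive* matrix whose tree topology is exactly the species
tree restricted to the non-anchor leaves — even though the individual
entries are "wrong" as distances.  More generally, for any additive matrix
and any transform `β + α·τ` (non-sister) / `β − f(τ)` (sister) with
`α, β > 0` and `f` increasing with `0 < f < β`, the anchored matrix is
additive for the correct restricted topology; the MSC case is `β = ln 3`,
`α = 1`, `f(x) = ln(3 − 2e^−x)`.  Neighbor joining (or any distance method
with a safety radius) applied to such matrices is therefore a statistically
consistent species-tree estimator.

The full pipeline deals with two practical issues:

* **Long branches** saturate the frequencies (many different long `τ` all
  give `p̂ ≈ 1`), so distances cannot rank them.  But long branches appear
  in most gene trees, so a strict-majority (>50 %) consensus recovers them
  directly; anchored distances are only used to resolve the consensus
  polytomies, with frequencies averaged over the clusters hanging off each
  polytomy.  Krichevsky–Trofimov add-half smoothing
  `p̂ = (c + 0.5)/(k + 1.5)` keeps every distance finite.
* **Cost** is controlled by sampling anchors: each round randomly matches
  the clusters of every polytomy into ⌈d/2⌉ pairs (all C(4,2) or C(5,2)
  pairs for degree-4/5 polytomies, which a double-anchored matrix cannot
  resolve), and each anchor pair helps resolve every polytomy on the path
  between its two species.  Per-anchor matrices are combined by entrywise
  averaging (*distance-sum*, the default) or via a compatibility supertree
  of per-anchor trees (*tree-sum*); the exhaustive *all-pairs* and
  *all-pairs-max* variants are also available.

## Worked example

```
$ distique simulate -n 8 -k 2000 --blen 0.5,2.0 --seed 1 \
      -o genes.nwk --true-tree true.nwk
wrote 2000 gene trees on 8 taxa to genes.nwk

$ distique infer -i genes.nwk -o species.nwk --seed 3
(t01,((((t02,t04),(t06,t07)),t05),t03),t08);

$ distique compare -t true.nwk -e species.nwk
0.000000
```

The first command draws a random 8-species tree with branch lengths uniform
in (0.5, 2) coalescent units and simulates 2000 coalescent gene trees.  The
second prints the estimated species-tree topology (branch lengths are
deliberately omitted: anchored distances preserve topology, not lengths).
The third reports the false-negative rate — the fraction of true internal
branches missing from the estimate, here 0.0, i.e. exact recovery.

Useful `infer` options: `--method distance-sum|tree-sum|all-pairs|all-pairs-max`,
`--rounds N` (anchor-sampling rounds, default 2), `--no-consensus`,
`--seed S`, `--report out.json` (machine-readable run summary), and
`--engine external:<path>` to delegate tree building from the exported
square-PHYLIP matrix to an external distance method.

The same functionality is available as a library:

```python
import numpy as np, distique as dq

rng = np.random.default_rng(1)
model = dq.random_species_tree(8, rng, (0.5, 2.0))
genes = dq.simulate_gene_trees(model, 2000, rng)
result = dq.run_distique(genes, seed=3)
print(result.tree.to_newick(lengths=False))
print(dq.fn_rate(model.tree, result.tree))   # 0.0
```

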