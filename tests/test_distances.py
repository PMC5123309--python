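"""Anchored distance transforms: quartet calls, the transform family, its
coalescent instantiation, and additivity."""

import itertools
import math

import numpy as np
import pytest

from distique import (DistanceMatrix, MSC_TRANSFORM, TransformSpec,
                      all_pairs_anchored, all_pairs_max, anchored_entry,
                      anchored_frequencies, double_anchored_from_matrix,
                      fn_rate, internal_path_length_matrix, is_additive,
                      msc_all_pairs, msc_double_anchored, neighbor_joining,
                      parse_newick, single_anchored)
from distique.distances import (NotAdditiveError, UnresolvedQuartetError,
                                quartet_topology_and_length, msc_transform)

from conftest import all_binary_topologies, quartet_topology_from_tree, random_binary_tree

ALT_TRANSFORM = TransformSpec(alpha=3.0, beta=2.0,
                              f=lambda x: 2.0 * (1.0 - math.exp(-x)))


class TestQuartetCall:
    def test_by_construction(self):
        D = DistanceMatrix.from_tree(parse_newick("((a:1,b:1):0.5,(c:1,d:1):0.5);"))
        topo, tau = quartet_topology_and_length(D, "abcd")
        assert frozenset(topo[0]) in ({frozenset("ab"), frozenset("cd")})
        assert tau == pytest.approx(1.0)

    def test_star_unresolved(self):
        data = np.full((4, 4), 2.0)
        np.fill_diagonal(data, 0.0)
        D = DistanceMatrix("abcd", data)
        with pytest.raises(UnresolvedQuartetError):
            quartet_topology_and_length(D, "abcd")

    def test_not_additive(self):
        D = DistanceMatrix.from_tree(parse_newick("((a:1,b:1):0.5,(c:1,d:1):0.5);"))
        D.set("a", "c", D["a", "c"] + 10.0)
        with pytest.raises(NotAdditiveError):
            quartet_topology_and_length(D, "abcd")

    def test_matches_tree_restriction(self, rng):
        for _ in range(5):
            t = random_binary_tree(8, rng)
            D = DistanceMatrix.from_tree(t)
            quartet = sorted(np.array(t.leaves)[rng.choice(8, 4, replace=False)])
            topo, tau = quartet_topology_and_length(D, quartet)
            assert frozenset(topo[0]) in (
                quartet_topology_from_tree(t, *quartet),
                frozenset(quartet) - quartet_topology_from_tree(t, *quartet))
            ip = internal_path_length_matrix(t.restrict(quartet))
            a, b = topo[0]
            c, d = topo[1]
            assert tau == pytest.approx(ip[a, c], abs=1e-9)


class TestAnchoredEntry:
    def test_msc_nonsister_value(self):
        got = anchored_entry(False, 1.0, MSC_TRANSFORM)
        assert got == pytest.approx(math.log(3) + 1.0, abs=1e-12)

    def test_msc_sister_equals_neg_log_concordance(self):
        # independent closed form: -ln(1 - (2/3) e^-1)
        got = anchored_entry(True, 1.0, MSC_TRANSFORM)
        assert got == pytest.approx(-math.log(1 - (2 / 3) * math.exp(-1)), abs=1e-12)

    @pytest.mark.parametrize("spec", [MSC_TRANSFORM, ALT_TRANSFORM])
    def test_sister_below_beta_nonsister_above(self, spec):
        for tau in (0.01, 0.5, 3.0):
            assert anchored_entry(True, tau, spec) < spec.beta
            assert anchored_entry(False, tau, spec) > spec.beta

    @pytest.mark.parametrize("spec", [MSC_TRANSFORM, ALT_TRANSFORM])
    def test_monotone_in_tau(self, spec):
        taus = np.linspace(0.01, 8, 50)
        sis = [anchored_entry(True, t, spec) for t in taus]
        non = [anchored_entry(False, t, spec) for t in taus]
        assert all(x > y for x, y in zip(sis, sis[1:]))  # decreasing
        assert all(x < y for x, y in zip(non, non[1:]))  # increasing

    def test_nonpositive_tau_raises(self):
        with pytest.raises(ValueError):
            anchored_entry(True, 0.0, MSC_TRANSFORM)

    def test_invalid_transform_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec(alpha=1.0, beta=1.0, f=lambda x: x).validate()
        with pytest.raises(ValueError):
            TransformSpec(alpha=-1.0, beta=1.0, f=lambda x: 0.5).validate()


class TestCoalescentTransformIdentity:
    def test_msc_transform_equals_neg_log_quartet_probs(self):
        spec = msc_transform()
        for tau in np.geomspace(0.01, 10.0, 60):
            lhs_sis = spec.beta - spec.f(tau)
            rhs_sis = -math.log(1.0 - (2.0 / 3.0) * math.exp(-tau))
            assert abs(lhs_sis - rhs_sis) < 1e-12
            lhs_non = spec.beta + spec.alpha * tau
            rhs_non = -math.log((1.0 / 3.0) * math.exp(-tau))
            assert abs(lhs_non - rhs_non) < 1e-12


@pytest.mark.parametrize("spec", [MSC_TRANSFORM, ALT_TRANSFORM],
                         ids=["msc", "alt"])
class TestAnchoredAdditivity:
    """Anchored matrices from an additive matrix are additive for the
    correctly restricted topology, for any valid transform."""

    def test_double_anchored(self, spec, rng):
        for _ in range(10):
            t = random_binary_tree(int(rng.integers(6, 10)), rng)
            D = DistanceMatrix.from_tree(t)
            u, v = np.array(t.leaves)[rng.choice(t.n_leaves, 2, replace=False)]
            Dd = double_anchored_from_matrix(D, u, v, spec)
            assert is_additive(Dd, 1e-8)
            assert fn_rate(t.restrict(Dd.labels), neighbor_joining(Dd)) == 0.0

    def test_double_anchored_sister_anchors(self, spec, rng):
        # anchors that are sisters in the tree still work
        t = parse_newick("(((a:.4,b:.3):.5,(c:.2,d:.6):.7):.3,(e:.2,f:.9):.4,g:1);")
        D = DistanceMatrix.from_tree(t)
        Dd = double_anchored_from_matrix(D, "a", "b", spec)
        assert is_additive(Dd, 1e-8)
        assert fn_rate(t.restrict(Dd.labels), neighbor_joining(Dd)) == 0.0

    def test_single_anchored(self, spec, rng):
        t = random_binary_tree(8, rng)
        v = t.leaves[3]
        Ds = single_anchored(DistanceMatrix.from_tree(t), v, spec)
        assert is_additive(Ds, 1e-8)
        assert fn_rate(t.restrict(Ds.labels), neighbor_joining(Ds)) == 0.0

    def test_all_pairs_anchored(self, spec, rng):
        t = random_binary_tree(7, rng)
        Da = all_pairs_anchored(DistanceMatrix.from_tree(t), spec)
        assert is_additive(Da, 1e-8)
        assert fn_rate(t, neighbor_joining(Da)) == 0.0


class TestAllPairsMax:
    def test_sisters_get_zero(self):
        t = parse_newick("(((a:1,b:1):0.3,c:1):0.7,(d:1,e:1):0.2,f:1);")
        Dm = all_pairs_max(DistanceMatrix.from_tree(t), MSC_TRANSFORM)
        assert Dm["a", "b"] == 0.0

    def test_caterpillar_internal_path(self):
        t = parse_newick("(((a:1,b:1):0.3,c:1):0.7,d:1,(e:1,f:1):0.2);")
        Dm = all_pairs_max(DistanceMatrix.from_tree(t), MSC_TRANSFORM)
        # a -> e crosses the 0.3, 0.7 and 0.2 internal branches
        assert Dm["a", "e"] == pytest.approx(1.2, abs=1e-9)

    def test_equals_internal_path_matrix(self, rng):
        for _ in range(5):
            t = random_binary_tree(8, rng)
            Dm = all_pairs_max(DistanceMatrix.from_tree(t), MSC_TRANSFORM)
            ip = internal_path_length_matrix(t)
            assert np.max(np.abs(Dm.data - ip.data)) < 1e-9


class TestMscEmpirical:
    def test_entries_are_neg_log_phat(self):
        gts = [parse_newick("((a,b),(u,v),x);") for _ in range(10)]
        table = anchored_frequencies(gts, "u", "v")
        D = msc_double_anchored(table)
        assert D["a", "b"] == pytest.approx(-math.log(10.5 / 11.5))

    def test_unobserved_entry_missing(self):
        gts = [parse_newick("((a,b),(u,v),x);")]
        table = anchored_frequencies(gts, "u", "v")
        table.labels.add("zz")
        D = msc_double_anchored(table)
        assert D.is_missing("a", "zz")
        assert not D.is_missing("a", "b")

    def test_no_signal_value_is_ln3(self):
        table = anchored_frequencies([parse_newick("((a,b),(u,v),x);")], "u", "v")
        assert -math.log(table.p_hat("a", "b")) < math.log(3)
        # prior-only pairs would sit exactly at beta = ln 3
        assert -math.log(1.0 / 3.0) == pytest.approx(math.log(3))

    def test_all_topologies_uniform_gives_six_ln3(self):
        # all 15 binary topologies on 5 leaves, once each: every quartet's
        # three topologies appear 5 times each, so p_hat = 5.5/16.5 = 1/3
        gts = all_binary_topologies("abcde")
        assert len(gts) == 15
        D = msc_all_pairs(gts)
        for pair in itertools.combinations("abcde", 2):
            assert D[pair] == pytest.approx(6.0 * math.log(3.0), abs=1e-12)

    def test_ordered_sum_is_twice_unordered(self):
        rng = np.random.default_rng(5)
        from distique import SpeciesTreeModel, simulate_gene_trees, random_species_tree
        model = random_species_tree(6, rng, (0.5, 2.0))
        gts = simulate_gene_trees(model, 50, rng)
        D = msc_all_pairs(gts)
        labels = model.tree.leaves
        a, b = labels[0], labels[1]
        unordered = 0.0
        for u, v in itertools.combinations([l for l in labels if l not in (a, b)], 2):
            table = anchored_frequencies(gts, u, v)
            unordered += -math.log(table.p_hat(a, b))
        assert D[a, b] == pytest.approx(2.0 * unordered)

    def test_identical_gene_trees_recover_species_tree(self, rng):
        t = random_binary_tree(7, rng)
        gts = [t.copy() for _ in range(200)]
        D = msc_all_pairs(gts)
        assert fn_rate(t, neighbor_joining(D)) == 0.0


class TestIsAdditive:
    def test_tree_matrix_true_perturbed_false(self, rng):
        t = random_binary_tree(8, rng)
        D = DistanceMatrix.from_tree(t)
        assert is_additive(D, 1e-8)
        D.set(t.leaves[0], t.leaves[4], D[t.leaves[0], t.leaves[4]] + 10.0)
        assert not is_additive(D, 1e-8)

    def test_agrees_with_per_quartet_checks(self, rng):
        t = random_binary_tree(7, rng)
        D = DistanceMatrix.from_tree(t)
        for quartet in itertools.combinations(t.leaves, 4):
            quartet_topology_and_length(D, quartet)  # no NotAdditiveError
        assert is_additive(D, 1e-8)

    def test_phylip_round_trip_shape(self, rng):
        t = random_binary_tree(6, rng)
        D = DistanceMatrix.from_tree(t)
        text = D.to_phylip()
        assert text.splitlines()[0].strip() == "6"
        assert len(text.splitlines()) == 7
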