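"""Tree substrate: newick I/O, bipartitions, FN rate, restriction, and the
path-attachment quartet kernel."""

import itertools

import dendropy
import numpy as np
import pytest

from distique import (NewickParseError, Tree, TreeError, fn_rate, parse_newick,
                      parse_newick_list, rf_distance, star,
                      tree_from_bipartitions)

from conftest import all_binary_topologies, quartet_topology_from_tree, random_binary_tree


class TestParseNewick:
    def test_basic_unrooted(self):
        t = parse_newick("((a,b),(c,d),e);")
        assert t.leaves == ["a", "b", "c", "d", "e"]
        assert t.bipartitions() == {frozenset("cd"), frozenset("cde")}

    def test_rooted_input_is_unrooted(self):
        t = parse_newick("((a,b),(c,d));")
        # rooted quartet collapses to the single internal edge
        assert t.bipartitions() == {frozenset("cd")}
        assert t.is_binary

    def test_length_round_trip(self):
        text = "((a:1,b:1):0.5,(c:1,d:1):0.5);"
        t = parse_newick(text)
        again = parse_newick(t.to_newick())
        assert again.bipartitions() == t.bipartitions()
        for pair in [("a", "b"), ("a", "c")]:
            from distique import DistanceMatrix
            assert DistanceMatrix.from_tree(again)[pair] == pytest.approx(
                DistanceMatrix.from_tree(t)[pair])

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            parse_newick("((a,b)")

    def test_duplicate_label_raises(self):
        with pytest.raises(TreeError):
            parse_newick("((a,a),(c,d),e);")

    def test_multi_tree_text(self):
        trees = parse_newick_list("((a,b),(c,d),e);\n((a,c),(b,d),e);\n")
        assert len(trees) == 2

    def test_round_trip_random_trees(self, rng):
        for _ in range(20):
            t = random_binary_tree(int(rng.integers(4, 15)), rng)
            back = parse_newick(t.to_newick())
            assert back.bipartitions() == t.bipartitions()

    def test_deterministic_output(self, rng):
        t = random_binary_tree(10, rng)
        assert t.to_newick() == parse_newick(t.to_newick()).to_newick()


class TestBipartitions:
    def test_star_has_none(self):
        assert star("abcde").bipartitions() == set()

    def test_binary_count_is_n_minus_3(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 20))
            t = random_binary_tree(n, rng)
            assert len(t.bipartitions()) == n - 3

    def test_agrees_with_dendropy_rf(self, rng):
        # independent oracle: dendropy's symmetric difference
        for _ in range(10):
            n = int(rng.integers(5, 12))
            t1, t2 = (random_binary_tree(n, rng) for _ in range(2))
            ours = rf_distance(t1, t2)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert ours == theirs


class TestFnRate:
    def test_identity_is_zero(self, rng):
        t = random_binary_tree(8, rng)
        assert fn_rate(t, t) == 0.0

    def test_one_nni_on_five_taxa(self):
        t1 = parse_newick("(((a,b),c),d,e);")
        t2 = parse_newick("(((a,c),b),d,e);")
        assert fn_rate(t1, t2) == 0.5
        assert fn_rate(t2, t1) == 0.5  # symmetric for binary trees

    def test_star_estimate_is_one(self):
        t = parse_newick("(((a,b),c),d,e);")
        assert fn_rate(t, star("abcde")) == 1.0

    def test_leaf_mismatch_raises(self):
        with pytest.raises(TreeError):
            fn_rate(parse_newick("((a,b),(c,d),e);"),
                    parse_newick("((a,b),(c,d),f);"))


class TestRestrict:
    def test_quartet_by_inspection(self):
        t = parse_newick("((a,b),(c,d),e);")
        sub = t.restrict("abcd")
        assert sub.bipartitions() == {frozenset("cd")}

    def test_restrict_to_all_is_identity(self, rng):
        t = random_binary_tree(9, rng)
        assert t.restrict(t.leaves).bipartitions() == t.bipartitions()

    def test_lengths_summed(self):
        t = parse_newick("((a:1,b:1):0.5,(c:1,d:1):0.5,e:9);")
        from distique import DistanceMatrix
        sub = t.restrict("abcd")
        assert DistanceMatrix.from_tree(sub)["a", "c"] == pytest.approx(3.0)

    def test_matches_quartet_consistency_bruteforce(self, rng):
        # induced 5-leaf topology agrees with every induced quartet
        for _ in range(5):
            t = random_binary_tree(10, rng)
            subset = sorted(np.array(t.leaves)[rng.choice(10, 5, replace=False)])
            sub = t.restrict(subset)
            for quartet in itertools.combinations(subset, 4):
                assert (quartet_topology_from_tree(sub, *quartet)
                        == quartet_topology_from_tree(t, *quartet))

    def test_unknown_leaf_raises(self):
        with pytest.raises(TreeError):
            parse_newick("((a,b),(c,d),e);").restrict(["a", "b", "z"])


class TestPathAttachment:
    def test_caterpillar_tokens(self):
        t = parse_newick("(((a,b),c),(d,(e,f)));")
        tok = t.path_attachment("a", "f")
        assert tok["b"] != tok["c"]
        assert tok["d"] != tok["e"]
        assert tok["b"] != tok["d"]

    def test_quartet_sisterhood(self):
        t = parse_newick("((a,b),(c,d));")
        tok = t.path_attachment("c", "d")
        assert tok["a"] == tok["b"]

    def test_exhaustive_against_restrict_n6(self):
        # every binary topology on 6 leaves, every anchor pair, every leaf pair
        labels = list("abcdef")
        for t in all_binary_topologies(labels):
            for u, v in itertools.combinations(labels, 2):
                tok = t.path_attachment(u, v)
                others = sorted(set(labels) - {u, v})
                for a, b in itertools.combinations(others, 2):
                    expected = quartet_topology_from_tree(t, a, b, u, v)
                    sisters = expected in (frozenset((a, b)), frozenset((u, v)))
                    assert (tok[a] == tok[b]) == sisters

    def test_polytomy_gives_shared_vertex_token(self):
        t = parse_newick("((a,b),c,d,e);")  # degree-4 polytomy
        tok = t.path_attachment("c", "d")
        # {a,e,c,d} is unresolved: same path vertex, different pendant edge
        assert tok["a"] != tok["e"] and tok["a"][0] == tok["e"][0]
        assert tok["a"] == tok["b"]  # ab.cd is resolved

    def test_missing_anchor_raises(self):
        with pytest.raises(TreeError):
            parse_newick("((a,b),(c,d),e);").path_attachment("a", "z")


class TestTreeFromBipartitions:
    def test_rebuilds_random_trees(self, rng):
        for _ in range(10):
            t = random_binary_tree(int(rng.integers(4, 12)), rng)
            rebuilt = tree_from_bipartitions(t.leaves, t.bipartitions())
            assert rebuilt.bipartitions() == t.bipartitions()

    def test_incompatible_raises(self):
        with pytest.raises(TreeError):
            tree_from_bipartitions("abcde",
                                   [frozenset("bc"), frozenset("cd")])
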