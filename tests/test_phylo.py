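import dendropy
import numpy as np
import pandas as pd
import pytest

from gatafam.phylo import (bootstrap_support, concat_alignment,
                           monophyly_test, nj_tree, pdistance_matrix,
                           read_newick, rf_distance, tree_splits,
                           write_newick)
from _oracles import patristic_from_newick, random_binary_tree


def df(D, labels):
    return pd.DataFrame(D, index=labels, columns=labels)


class TestPDistance:
    def test_identical_sequences_zero(self):
        D = pdistance_matrix({"a": "ACGT", "b": "ACGT"})
        assert D.loc["a", "b"] == 0

    def test_quarter_difference(self):
        D = pdistance_matrix({"a": "AAAA", "b": "AAAT"})
        assert D.loc["a", "b"] == 0.25

    def test_pairwise_gap_deletion(self):
        D = pdistance_matrix({"a": "A-CGT", "b": "ATCGA"})
        assert D.loc["a", "b"] == 0.25    # 1 of 4 comparable columns

    def test_random_pair_equals_bruteforce_count(self):
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list("ACGT-"), size=300))
        b = "".join(rng.choice(list("ACGT-"), size=300))
        valid = [(x, y) for x, y in zip(a, b) if "-" not in (x, y)]
        expected = sum(x != y for x, y in valid) / len(valid)
        assert pdistance_matrix({"a": a, "b": b}).loc["a", "b"] == \
            pytest.approx(expected)


class TestNeighborJoining:
    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_additive_matrix_recovers_tree_and_lengths(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(5):
            newick = random_binary_tree(labels, rng)
            names, D = patristic_from_newick(newick)
            tree = nj_tree(df(D, names))
            assert rf_distance(tree, read_newick(newick)) == 0
            # patristic distances of the reconstruction match the input
            back_names, Dback = _patristic_of(tree)
            order = [back_names.index(n) for n in names]
            assert np.allclose(Dback[np.ix_(order, order)], D, atol=1e-6)

    def test_three_taxa_closed_form(self):
        D = df([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = nj_tree(D)
        lengths = {l.taxon.label: l.edge.length
                   for l in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_matches_independent_nj_implementation(self):
        rng = np.random.default_rng(17)
        n = 7
        labels = [f"t{i}" for i in range(n)]
        M = rng.uniform(0.2, 1.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        mine = nj_tree(df(D, labels))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            __import__("io").StringIO(
                "," + ",".join(labels) + "\n" + "\n".join(
                    labels[i] + "," + ",".join(str(x) for x in D[i])
                    for i in range(n))), delimiter=",")
        theirs = pdm.nj_tree()
        assert tree_splits(mine) == tree_splits(theirs)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(df([[0, 1], [1, 0]], ["a", "b"]))


def _patristic_of(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    D = np.zeros((len(labels), len(labels)))
    tns = tree.taxon_namespace
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                D[i, j] = pdm.patristic_distance(tns.get_taxon(a),
                                                 tns.get_taxon(b))
    return labels, D


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = read_newick("((a,b),(c,d));")
        assert rf_distance(t, read_newick("((a,b),(c,d));")) == 0

    def test_two_resolved_four_taxon_trees(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_matches_dendropy_on_random_trees(self):
        rng = np.random.default_rng(12)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(10):
            n1 = random_binary_tree(labels, rng)
            n2 = random_binary_tree(labels, rng)
            t1, t2 = read_newick(n1), read_newick(n2)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=n1, schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=n2, schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(
                d1, d2)
            assert rf_distance(t1, t2) == expected

    def test_upper_bound_fully_resolved(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(8)]
        t1 = read_newick(random_binary_tree(labels, rng))
        t2 = read_newick(random_binary_tree(labels, rng))
        assert rf_distance(t1, t2) <= 2 * (8 - 3)

    def test_different_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(read_newick("((a,b),(c,d));"),
                        read_newick("((a,b),(c,e));"))


class TestBootstrap:
    def _two_clade_msa(self, n_fixed=40, n_noise=10, seed=0):
        rng = np.random.default_rng(seed)
        taxa = {f"a{i}": [] for i in range(3)} | {f"b{i}": [] for i in range(3)}
        for _ in range(n_fixed):
            for t in taxa:
                taxa[t].append("A" if t.startswith("a") else "C")
        for _ in range(n_noise):
            for t in taxa:
                taxa[t].append(str(rng.choice(list("ACGT"))))
        return {t: "".join(v) for t, v in taxa.items()}

    def test_clear_clades_get_high_support(self):
        msa = self._two_clade_msa()
        tree = bootstrap_support(msa, B=200, seed=5)
        supports = [float(n.label) for n in tree.preorder_node_iter()
                    if n.label]
        split = frozenset({"a0", "a1", "a2"})
        other = frozenset({"b0", "b1", "b2"})
        assert split in tree_splits(tree) or other in tree_splits(tree)
        assert max(supports) >= 95

    def test_same_seed_identical_supports(self):
        msa = self._two_clade_msa(seed=2)
        t1 = bootstrap_support(msa, B=50, seed=9)
        t2 = bootstrap_support(msa, B=50, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_different_seed_may_differ_but_same_topology(self):
        msa = self._two_clade_msa(seed=2)
        t1 = bootstrap_support(msa, B=50, seed=1)
        t2 = bootstrap_support(msa, B=50, seed=2)
        assert tree_splits(t1) == tree_splits(t2)


class TestConcat:
    def test_widths_and_partitions(self):
        g1 = {"a": "A" * 10, "b": "C" * 10}
        g2 = {"a": "G" * 15, "b": "T" * 15}
        sm, parts = concat_alignment({"g1": g1, "g2": g2}, ["g1", "g2"])
        assert len(sm["a"]) == 25
        assert parts == [("g1", 1, 10), ("g2", 11, 25)]

    def test_missing_taxon_named_in_error(self):
        g1 = {"a": "AA", "b": "CC"}
        g2 = {"a": "GG"}
        with pytest.raises(ValueError, match="'b'.*'g2'"):
            concat_alignment({"g1": g1, "g2": g2})


class TestMonophyly:
    TREE = "(out,((r1,(r2,r3)),((x1,x2),(y1,y2))));"

    def test_planted_clade_is_monophyletic(self):
        t = read_newick(self.TREE)
        res = monophyly_test(t, {"R": ["r1", "r2", "r3"]}, outgroup="out")
        assert res["R"] is True

    def test_scattered_group_is_not(self):
        t = read_newick(self.TREE)
        res = monophyly_test(t, {"S": ["r1", "x1", "y1"]}, outgroup="out")
        assert res["S"] is False

    def test_singleton_group_trivially_monophyletic(self):
        t = read_newick(self.TREE)
        assert monophyly_test(t, {"one": ["x1"]})["one"] is True

    def test_unknown_member_rejected(self):
        with pytest.raises(ValueError):
            monophyly_test(read_newick(self.TREE), {"g": ["nope"]})


class TestNewickRoundTrip:
    def test_round_trip_stable(self, tmp_path):
        t = read_newick("((a:1,b:2):0.5,(c:1,d:1):0.5);")
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert tree_splits(back) == tree_splits(t)
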