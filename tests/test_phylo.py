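import dendropy
import numpy as np
import pytest

from nsltp.phylo import (
    DistanceMatrix,
    clade_purity,
    is_monophyletic,
    neighbor_joining,
    pdistance_matrix,
    tree_to_newick,
)
from nsltp.sequence_io import GeneRecord

from conftest import random_additive_tree


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for ta in tree.taxon_namespace:
        for tb in tree.taxon_namespace:
            if ta.label < tb.label:
                out[(ta.label, tb.label)] = pdm.distance(ta, tb)
    return out


def bipartitions(tree):
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.postorder_internal_node_iter():
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) >= 2 and len(leaves - below) >= 2:
            out.add(min(below, leaves - below, key=sorted))
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        got = patristic(tree)
        assert got[("A", "B")] == pytest.approx(5)
        assert got[("A", "C")] == pytest.approx(9)
        assert got[("B", "C")] == pytest.approx(10)

    def test_four_taxa_additive_recovery(self):
        d = np.array(
            [[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 7], [7, 8, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        got = patristic(tree)
        for (x, y), val in got.items():
            i, j = "ABCD".index(x), "ABCD".index(y)
            assert val == pytest.approx(d[i, j])
        assert bipartitions(tree) == {frozenset({"A", "B"})}

    def test_identical_rows_join_first(self):
        d = np.array(
            [[0, 0.0, 0.9, 0.8],
             [0.0, 0, 0.9, 0.8],
             [0.9, 0.9, 0, 0.5],
             [0.8, 0.8, 0.5, 0]]
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert frozenset({"A", "B"}) in bipartitions(tree)

    def test_non_symmetric_errors(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], float)
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(list("ABC"), d))

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_trees_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        nwk, labels, d = random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        got = patristic(tree)
        for x in range(n):
            for y in range(x + 1, n):
                assert got[(labels[x], labels[y])] == pytest.approx(d[x, y]), (
                    seed, labels[x], labels[y],
                )
        ref = dendropy.Tree.get(data=nwk, schema="newick",
                                taxon_namespace=tree.taxon_namespace)
        assert bipartitions(tree) == bipartitions(ref)

    def test_total_length_non_negative_and_leaves_preserved(self):
        rng = np.random.default_rng(33)
        _, labels, d = random_additive_tree(rng, 6)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert sorted(lf.taxon.label for lf in tree.leaf_node_iter()) == sorted(labels)
        assert all(
            e.length is None or e.length >= 0 for e in tree.preorder_edge_iter()
        )

    def test_newick_round_trip(self):
        rng = np.random.default_rng(2)
        _, labels, d = random_additive_tree(rng, 5)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        nwk = tree_to_newick(tree)
        back = dendropy.Tree.get(data=nwk, schema="newick")
        assert bipartitions(back) == bipartitions(tree)
        assert patristic(back) == pytest.approx(patristic(tree))

    def test_agrees_with_skbio(self):
        # independent NJ implementation as cross-check
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        _, labels, d = random_additive_tree(rng, 7)
        mine = neighbor_joining(DistanceMatrix(labels, d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        ref = dendropy.Tree.get(data=str(theirs), schema="newick",
                                taxon_namespace=mine.taxon_namespace)
        assert bipartitions(mine) == bipartitions(ref)


class TestPDistance:
    def test_identical_sequences_zero(self):
        recs = [GeneRecord(f"g{i}", protein_seq="MKVLACDEFG") for i in range(3)]
        dm = pdistance_matrix(recs)
        assert np.allclose(dm.d, 0)

    def test_one_in_ten_mismatch(self):
        recs = [
            GeneRecord("a", protein_seq="MKVLACDEFG"),
            GeneRecord("b", protein_seq="MKVLACDEWG"),
            GeneRecord("c", protein_seq="MKVLACDEFG"),
        ]
        dm = pdistance_matrix(recs)
        i, j = dm.labels.index("a"), dm.labels.index("b")
        assert dm.d[i, j] == pytest.approx(0.1)

    def test_too_few_errors(self):
        with pytest.raises(ValueError):
            pdistance_matrix([GeneRecord("a", protein_seq="MK")])


class TestCladePurity:
    def make_tree(self, nwk, labels):
        tns = dendropy.TaxonNamespace(labels)
        return dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)

    def test_coherent_types_monophyletic(self):
        tree = self.make_tree("((a1:1,a2:1):2,(b1:1,(b2:1,b3:1):1):2);",
                              ["a1", "a2", "b1", "b2", "b3"])
        report = clade_purity(tree, {
            "a1": "I", "a2": "I", "b1": "II", "b2": "II", "b3": "II",
        })
        assert report == {"I": True, "II": True}

    def test_scattered_type_not_monophyletic(self):
        tree = self.make_tree("((a1:1,b1:1):2,(a2:1,b2:1):2);",
                              ["a1", "b1", "a2", "b2"])
        report = clade_purity(tree, {
            "a1": "I", "a2": "I", "b1": "II", "b2": "II",
        })
        assert report["I"] is False and report["II"] is False

    def test_singleton_trivially_monophyletic(self):
        tree = self.make_tree("((a1:1,a2:1):2,(b1:1,c1:1):2);",
                              ["a1", "a2", "b1", "c1"])
        report = clade_purity(tree, {
            "a1": "I", "a2": "I", "b1": "II", "c1": "V",
        })
        assert report["II"] is True and report["V"] is True

    def test_unclassified_leaves_ignored(self):
        tree = self.make_tree("((a1:1,u1:1):2,(a2:1,b1:1):2);",
                              ["a1", "u1", "a2", "b1"])
        report = clade_purity(tree, {
            "a1": "I", "a2": "I", "u1": "unclassified", "b1": "II",
        })
        # with u1 pruned, a1+a2 form one side of a bipartition
        assert report["I"] is True

    def test_missing_assignment_errors(self):
        tree = self.make_tree("((a1:1,a2:1):2,b1:2);", ["a1", "a2", "b1"])
        with pytest.raises(ValueError):
            clade_purity(tree, {"a1": "I"})

    def test_generated_family_types_cluster(self, family_fixture):
        # strong within-type similarity: same spacing backbone per type
        from nsltp.synthetic import FamilySpec, gen_family

        records, truth = gen_family(
            FamilySpec(type_counts={"I": 4, "II": 4, "V": 4}, seed=2)
        )
        recs = [GeneRecord(g, protein_seq=s) for g, s in records]
        tree = neighbor_joining(pdistance_matrix(recs))
        types = dict(zip(truth.gene_id, truth.true_type))
        report = clade_purity(tree, types)
        assert report == {"I": True, "II": True, "V": True}
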