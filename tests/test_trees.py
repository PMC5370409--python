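"""Neighbor joining, binary-matrix distances, Robinson-Foulds, clades."""

import random

import dendropy
import numpy as np
import pytest

from mitevol.hce import BinaryMatrix
from mitevol.trees import (
    DistanceMatrix,
    binary_distance,
    clade_check,
    neighbor_joining,
    rf_distance,
)


def random_binary_tree(rng, n):
    taxa = [f"T{i:02d}" for i in range(n)]
    frag = {t: t for t in taxa}
    act = taxa[:]
    while len(act) > 1:
        a = act.pop(rng.randrange(len(act)))
        b = act.pop(rng.randrange(len(act)))
        key = min(a, b)
        frag[key] = (f"({frag[a]}:{rng.uniform(0.1, 2):.4f},"
                     f"{frag[b]}:{rng.uniform(0.1, 2):.4f})")
        act.append(key)
    return dendropy.Tree.get(data=frag[act[0]] + ";", schema="newick")


def patristic_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda x: x.label)
    d = np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
    return DistanceMatrix([x.label for x in taxa], d)


class TestDistanceMatrixType:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], [[0, 1], [2, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], [[1, 1], [1, 0]])
        with pytest.raises(ValueError, match="unique"):
            DistanceMatrix(["a", "a"], [[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="NaN"):
            DistanceMatrix(["a", "b"], [[0, np.nan], [np.nan, 0]])

    def test_tsv_round_trip(self, tmp_path):
        m = DistanceMatrix(["a", "b", "c"],
                           [[0, 1.5, 2], [1.5, 0, 3.25], [2, 3.25, 0]])
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.labels == m.labels
        assert np.allclose(back.d, m.d)


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # distances generated from ((A:1,B:2):1,(C:3,D:1))
        d = np.array([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
                     float)
        t = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        ref = dendropy.Tree.get(data="((A:1,B:2):1,(C:3,D:1));", schema="newick")
        assert rf_distance(t, ref) == 0
        lengths = {x.taxon.label: x.edge.length for x in t.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = neighbor_joining(DistanceMatrix(["X", "Y", "Z"], d))
        lengths = {x.taxon.label: x.edge.length for x in t.leaf_node_iter()}
        assert lengths["X"] == pytest.approx((2 + 3 - 5) / 2)
        assert lengths["Y"] == pytest.approx((2 + 5 - 3) / 2)
        assert lengths["Z"] == pytest.approx((3 + 5 - 2) / 2)

    def test_ultrametric_tie_broken_deterministically(self):
        d = np.ones((4, 4)) - np.eye(4)
        m = DistanceMatrix(list("ABCD"), d)
        t1 = neighbor_joining(m)
        t2 = neighbor_joining(m)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        total = sum(e.length for e in t1.preorder_edge_iter()
                    if e.length is not None)
        assert total == pytest.approx(2.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], [[0, 1], [1, 0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_consistency_random_trees(self, seed):
        rng = random.Random(seed)
        tree = random_binary_tree(rng, rng.randint(4, 12))
        rec = neighbor_joining(patristic_matrix(tree))
        assert rf_distance(rec, tree) == 0

    def test_agrees_with_independent_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = random.Random(42)
        tree = random_binary_tree(rng, 8)
        m = patristic_matrix(tree)
        mine = neighbor_joining(m)
        other = dendropy.Tree.get(data=str(sknj(SkDM(m.d, m.labels))),
                                  schema="newick")
        assert rf_distance(mine, other) == 0


class TestBinaryDistance:
    def test_identical_rows_zero(self):
        m = BinaryMatrix(["r1", "r2", "r3"], [1, 2],
                         [[1, 0], [1, 0], [0, 1]])
        assert binary_distance(m)[("r1", "r2")] == 0

    def test_hand_counts(self):
        m = BinaryMatrix(["r1", "r2"], [1, 2, 3, 4], [[1, 1, 0, 0], [0, 0, 1, 1]])
        assert binary_distance(m, "hamming")[("r1", "r2")] == 4
        assert binary_distance(m, "jaccard")[("r1", "r2")] == pytest.approx(1.0)

    def test_single_column_complement(self):
        m = BinaryMatrix(["r1", "r2"], [1], [[1], [0]])
        assert binary_distance(m, "hamming")[("r1", "r2")] == 1


class TestRobinsonFoulds:
    t_ab = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")

    def test_self_distance_zero(self):
        assert rf_distance(self.t_ab, self.t_ab) == 0

    def test_two_quartet_topologies(self):
        other = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
        assert rf_distance(self.t_ab, other) == 2

    def test_star_vs_resolved(self):
        star = dendropy.Tree.get(data="(A,B,C,D);", schema="newick")
        assert rf_distance(star, self.t_ab) == 1

    def test_leaf_set_mismatch_rejected(self):
        other = dendropy.Tree.get(data="((A,B),(C,E));", schema="newick")
        with pytest.raises(ValueError):
            rf_distance(self.t_ab, other)

    @pytest.mark.parametrize("seed", range(3))
    def test_metric_properties(self, seed):
        rng = random.Random(seed)
        trees = [random_binary_tree(random.Random(seed * 10 + i), 7)
                 for i in range(3)]
        a, b, c = trees
        assert rf_distance(a, b) == rf_distance(b, a)
        assert rf_distance(a, a) == 0
        assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)


class TestCladeCheck:
    tree = dendropy.Tree.get(data="(((A,B),C),(D,E));", schema="newick")

    def test_cherry_is_clade(self):
        assert clade_check(self.tree, {"g": ["A", "B"]})["g"]

    def test_full_leaf_set_by_convention(self):
        assert clade_check(self.tree, {"g": list("ABCDE")})["g"]

    def test_interleaved_group_not_clade(self):
        assert not clade_check(self.tree, {"g": ["A", "D"]})["g"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            clade_check(self.tree, {"g": ["A", "Z"]})
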