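"""Neighbor-joining construction, Newick round-trips and tree cutting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from mnpkit.genotyping import CoreSet, GenotypeTable
from mnpkit.io_formats import SampleRecord, write_newick
from mnpkit.phylogeny import (
    DistanceMatrix,
    annotate_leaves,
    distance_from_gs,
    distance_pdist,
    nj_tree,
    path_length_matrix,
    read_newick,
    to_newick,
    tree_cut_partition,
)
from mnpkit.similarity import GsMatrix


def random_additive_case(rng, n):
    """A random binary tree with positive branch lengths and its tip-tip
    distance matrix — the independent oracle for NJ recovery."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = round(float(rng.uniform(0.05, 1.0)), 6)
        b.length = round(float(rng.uniform(0.05, 1.0)), 6)
        parent = TreeNode(children=[a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    for x in nodes:
        x.length = round(float(rng.uniform(0.05, 1.0)), 6)
    tree = TreeNode(children=nodes)
    skdm = tree.tip_tip_distances()
    order = sorted(skdm.ids)
    d = np.array([[skdm[a, b] for b in order] for a in order])
    return DistanceMatrix(order, d)


class TestNjTree:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(list("ABC"), d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)   # 2
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)   # 3
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)   # 7

    def test_two_taxon_trivial_tree(self):
        tree = nj_tree(DistanceMatrix(["A", "B"], np.array([[0.0, 4.0], [4.0, 0.0]])))
        assert sorted(t.name for t in tree.tips()) == ["A", "B"]
        assert path_length_matrix(tree).d[0, 1] == pytest.approx(4.0)

    def test_single_taxon_errors(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A"], np.zeros((1, 1))))

    @pytest.mark.parametrize("n", [4, 5, 7, 10])
    def test_additive_matrix_recovered_exactly(self, n):
        """On additive matrices NJ path lengths reproduce the input."""
        rng = np.random.default_rng(n)
        for _ in range(20):
            dm = random_additive_case(rng, n)
            tree = nj_tree(dm)
            out = path_length_matrix(tree)
            order = [out.samples.index(s) for s in dm.samples]
            np.testing.assert_allclose(out.d[np.ix_(order, order)], dm.d, atol=1e-9)

    def test_agrees_with_skbio_nj_on_additive_matrix(self):
        """Independent implementation cross-check: identical tip-tip metrics."""
        rng = np.random.default_rng(42)
        dm = random_additive_case(rng, 8)
        mine = path_length_matrix(nj_tree(dm))
        other = skbio_nj(SkbioDM(dm.d, ids=dm.samples)).tip_tip_distances()
        for a, b in itertools.combinations(dm.samples, 2):
            i, j = mine.samples.index(a), mine.samples.index(b)
            assert mine.d[i, j] == pytest.approx(other[a, b], abs=1e-9)

    def test_negative_branch_lengths_clamped(self):
        # strongly non-additive matrix provokes negative two-point estimates
        d = np.array([[0, 1, 9, 9], [1, 0, 1, 9], [9, 1, 0, 1], [9, 9, 1, 0]],
                     dtype=float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0

    def test_order_invariance_without_ties(self):
        rng = np.random.default_rng(5)
        dm = random_additive_case(rng, 6)
        perm = rng.permutation(len(dm.samples))
        dm2 = DistanceMatrix([dm.samples[i] for i in perm],
                             dm.d[np.ix_(perm, perm)])
        m1, m2 = path_length_matrix(nj_tree(dm)), path_length_matrix(nj_tree(dm2))
        for a, b in itertools.combinations(dm.samples, 2):
            v1 = m1.d[m1.samples.index(a), m1.samples.index(b)]
            v2 = m2.d[m2.samples.index(a), m2.samples.index(b)]
            assert v1 == pytest.approx(v2, abs=1e-9)

    def test_tie_break_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)  # all Q values tie
        t1 = to_newick(nj_tree(DistanceMatrix(list("ABCD"), d)))
        t2 = to_newick(nj_tree(DistanceMatrix(list("ABCD"), d)))
        assert t1 == t2


class TestDistances:
    def test_gs_complement(self):
        gsm = GsMatrix(["a", "b"], np.array([[1.0, 0.4], [0.4, 1.0]]), m=10)
        dm = distance_from_gs(gsm)
        assert dm.d[0, 1] == pytest.approx(0.6)
        ident = GsMatrix(["a", "b"], np.ones((2, 2)), m=10)
        assert distance_from_gs(ident).d[0, 1] == 0.0

    def test_pdist_hand_count(self):
        df = pd.DataFrame({"M1": ["ACG", "ACG"], "M2": ["TTT", "TAT"],
                           "M3": ["GG", "CC"]}, index=["a", "b"])
        df.index.name = "sample"
        dm = distance_pdist(GenotypeTable(df), CoreSet(["M1", "M2", "M3"]))
        # mismatches: 0 + 1 + 2 = 3 of 8 concatenated sites
        assert dm.d[0, 1] == pytest.approx(3 / 8)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestNewick:
    def test_round_trip_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(9)
        dm = random_additive_case(rng, 6)
        tree = nj_tree(dm)
        write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        orig = path_length_matrix(tree)
        rt = path_length_matrix(back)
        for a, b in itertools.combinations(dm.samples, 2):
            v1 = orig.d[orig.samples.index(a), orig.samples.index(b)]
            v2 = rt.d[rt.samples.index(a), rt.samples.index(b)]
            assert v2 == pytest.approx(v1, abs=1e-5)  # 6-decimal serialization

    def test_six_decimal_format(self):
        tree = nj_tree(DistanceMatrix(list("ABC"),
                                      np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]],
                                               dtype=float)))
        assert ":2.000000" in to_newick(tree)


class TestTreeCut:
    def _blocky_tree(self):
        # three well-separated groups of leaves
        names = ["a1", "a2", "a3", "b1", "b2", "c1", "c2", "c3"]
        group = {n: n[0] for n in names}
        n = len(names)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = 0.05 if group[names[i]] == group[names[j]] else 1.0
        return names, nj_tree(DistanceMatrix(names, d)), group

    def test_k1_single_cluster(self):
        names, tree, _ = self._blocky_tree()
        part = tree_cut_partition(tree, 1)
        assert set(part.values()) == {"C1"} and set(part) == set(names)

    def test_k_equals_leaves_gives_singletons(self):
        names, tree, _ = self._blocky_tree()
        part = tree_cut_partition(tree, len(names))
        assert len(set(part.values())) == len(names)

    def test_planted_groups_recovered(self):
        names, tree, group = self._blocky_tree()
        part = tree_cut_partition(tree, 3)
        for a, b in itertools.combinations(names, 2):
            assert (part[a] == part[b]) == (group[a] == group[b])

    def test_k_out_of_range(self):
        _, tree, _ = self._blocky_tree()
        for bad in (0, 99):
            with pytest.raises(ValueError):
                tree_cut_partition(tree, bad)


class TestAnnotateLeaves:
    def _tree(self):
        return nj_tree(DistanceMatrix(
            list("ABC"), np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float)))

    def test_full_metadata_rows(self, tmp_path):
        meta = {s: SampleRecord(s, "cultivar", cap_color="white") for s in "ABC"}
        rows = annotate_leaves(self._tree(), meta, {"A": "G1", "B": "G1", "C": "G2"},
                               tmp_path / "ann.tsv")
        assert len(rows) == 3
        by_leaf = {r["leaf"]: r for r in rows}
        assert by_leaf["C"]["pedigree"] == "G2"
        assert by_leaf["A"]["cap_color"] == "white"
        header = (tmp_path / "ann.tsv").read_text().splitlines()[0]
        assert header == "leaf\tpedigree\tcap_color\tsource"

    def test_missing_metadata_names_leaf(self):
        meta = {s: SampleRecord(s, "wild") for s in "AB"}
        with pytest.raises(KeyError, match="C"):
            annotate_leaves(self._tree(), meta, {})
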