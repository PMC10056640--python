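"""Genetic-similarity computation, pair classification and pedigree grouping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnpkit.genotyping import CoreSet, GenotypeTable
from mnpkit.similarity import (
    DIFFERENT_PEDIGREE,
    SAME_CULTIVAR,
    SAME_PEDIGREE,
    GsMatrix,
    classify_pair,
    gs_matrix,
    gs_pair,
    pedigree_partition,
    pedigree_stats,
)

EPS = 1e-9


def gsm_from(samples, mat):
    return GsMatrix(samples=samples, gs=np.asarray(mat, dtype=float), m=100)


class TestGsPair:
    def test_identity(self):
        row = ["A" * 10] * 69
        assert gs_pair(row, row, 69) == 1.0

    def test_42_of_69(self):
        a = [f"H{i}" for i in range(69)]
        b = a[:42] + [f"X{i}" for i in range(27)]
        assert gs_pair(a, b) == pytest.approx(42 / 69)

    def test_all_differ(self):
        assert gs_pair(["AA", "CC"], ["GG", "TT"]) == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            gs_pair(["AA"], ["AA", "CC"])

    def test_iupac_symbols_compare_exactly(self):
        assert gs_pair(["ARGT"], ["AAGT"]) == 0.0
        assert gs_pair(["ARGT"], ["ARGT"]) == 1.0


class TestGsMatrix:
    def _table(self, rows, markers):
        df = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
        df.index.name = "sample"
        return GenotypeTable(df)

    def test_identical_samples(self):
        t = self._table({"a": ["AA"], "b": ["AA"]}, ["M1"])
        gsm = gs_matrix(t)
        np.testing.assert_allclose(gsm.gs, [[1, 1], [1, 1]])

    def test_three_sample_hand_computation(self):
        t = self._table(
            {"a": ["AA", "CC", "GG"], "b": ["AA", "CC", "TT"], "c": ["AA", "GG", "TT"]},
            ["M1", "M2", "M3"])
        gsm = gs_matrix(t)
        assert gsm.value("a", "b") == pytest.approx(2 / 3)
        assert gsm.value("a", "c") == pytest.approx(1 / 3)
        assert gsm.value("b", "c") == pytest.approx(2 / 3)

    def test_symmetric_unit_diagonal_k_over_m(self):
        t = self._table({"a": ["AA", "CC"], "b": ["AA", "TT"], "c": ["GG", "TT"]},
                        ["M1", "M2"])
        gsm = gs_matrix(t)
        np.testing.assert_allclose(gsm.gs, gsm.gs.T)
        np.testing.assert_allclose(np.diag(gsm.gs), 1.0)
        ks = gsm.gs * gsm.m
        np.testing.assert_allclose(ks, np.round(ks))

    def test_permutation_consistency(self):
        t = self._table({"a": ["AA", "CC"], "b": ["AA", "TT"], "c": ["GG", "TT"]},
                        ["M1", "M2"])
        perm = GenotypeTable(t.data.iloc[[2, 0, 1]])
        g1, g2 = gs_matrix(t), gs_matrix(perm)
        for x, y in itertools.combinations("abc", 2):
            assert g1.value(x, y) == g2.value(x, y)

    def test_core_restriction(self):
        t = self._table({"a": ["AA", "CC"], "b": ["AA", "TT"]}, ["M1", "M2"])
        gsm = gs_matrix(t, CoreSet(["M1"]))
        assert gsm.m == 1 and gsm.value("a", "b") == 1.0


class TestClassifyPair:
    @pytest.mark.parametrize("gs,verdict", [
        (0.0, DIFFERENT_PEDIGREE),
        (0.60, DIFFERENT_PEDIGREE),          # boundary: ≤ 0.60 separates pedigrees
        (0.60 + EPS, SAME_PEDIGREE),
        (0.80, SAME_PEDIGREE),
        (0.986, SAME_PEDIGREE),              # boundary: ≤ 0.986 still two cultivars
        (0.986 + EPS, SAME_CULTIVAR),
        (1.0, SAME_CULTIVAR),
    ])
    def test_threshold_boundaries(self, gs, verdict):
        assert classify_pair(gs).verdict == verdict

    def test_near_identity_annotation(self):
        assert classify_pair(0.99).near_identity
        assert not classify_pair(1.0).near_identity
        assert not classify_pair(0.5).near_identity

    def test_out_of_range_errors(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                classify_pair(bad)


class TestPedigreePartition:
    def test_planted_blocks(self):
        gs = [[1.0, 0.9, 0.3, 0.3],
              [0.9, 1.0, 0.3, 0.3],
              [0.3, 0.3, 1.0, 0.9],
              [0.3, 0.3, 0.9, 1.0]]
        part = pedigree_partition(gsm_from(list("abcd"), gs))
        assert part["a"] == part["b"] != part["c"] == part["d"]

    def test_all_below_threshold_singletons(self):
        gs = np.full((3, 3), 0.60)
        np.fill_diagonal(gs, 1.0)
        part = pedigree_partition(gsm_from(list("abc"), gs))
        assert len(set(part.values())) == 3

    def test_chained_pairs_single_linkage_closure(self):
        gs = [[1.0, 0.7, 0.5],
              [0.7, 1.0, 0.7],
              [0.5, 0.7, 1.0]]
        part = pedigree_partition(gsm_from(list("abc"), gs))
        assert len(set(part.values())) == 1

    def test_complete_linkage_splits_chain(self):
        gs = [[1.0, 0.7, 0.5],
              [0.7, 1.0, 0.7],
              [0.5, 0.7, 1.0]]
        part = pedigree_partition(gsm_from(list("abc"), gs), linkage_mode="complete")
        assert len(set(part.values())) == 2

    def test_labels_by_size_then_lexicographic(self):
        gs = np.full((5, 5), 0.2)
        np.fill_diagonal(gs, 1.0)
        for i, j in [(3, 4)]:
            gs[i, j] = gs[j, i] = 0.9
        part = pedigree_partition(gsm_from(list("abcde"), gs))
        assert part["d"] == part["e"] == "G1"  # biggest group first
        assert part["a"] == "G2"               # then lexicographic smallest member

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_union_find_oracle(self, data):
        """Partition equals a brute-force union-find closure of GS > θ edges."""
        n = data.draw(st.integers(2, 12))
        vals = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n * (n - 1) // 2,
            max_size=n * (n - 1) // 2))
        gs = np.eye(n)
        iu = np.triu_indices(n, 1)
        gs[iu] = vals
        gs = np.maximum(gs, gs.T)
        np.fill_diagonal(gs, 1.0)
        samples = [f"s{i:02d}" for i in range(n)]
        part = pedigree_partition(gsm_from(samples, gs))

        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in itertools.combinations(range(n), 2):
            if gs[i, j] > 0.60:
                parent[find(i)] = find(j)
        for i, j in itertools.combinations(range(n), 2):
            same_oracle = find(i) == find(j)
            assert (part[samples[i]] == part[samples[j]]) == same_oracle

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        n = 8
        gs = np.eye(n)
        iu = np.triu_indices(n, 1)
        gs[iu] = rng.random(len(iu[0]))
        gs = np.maximum(gs, gs.T)
        np.fill_diagonal(gs, 1.0)
        samples = [f"s{i}" for i in range(n)]
        part1 = pedigree_partition(gsm_from(samples, gs))
        order = rng.permutation(n)
        part2 = pedigree_partition(
            gsm_from([samples[i] for i in order], gs[np.ix_(order, order)]))
        groups1 = {frozenset(s for s in samples if part1[s] == g) for g in part1.values()}
        groups2 = {frozenset(s for s in samples if part2[s] == g) for g in part2.values()}
        assert groups1 == groups2


class TestPedigreeStats:
    def test_planted_pedigree_mean(self):
        gs = [[1.0, 0.90, 0.92],
              [0.90, 1.0, 0.94],
              [0.92, 0.94, 1.0]]
        gsm = gsm_from(list("abc"), gs)
        stats, between = pedigree_stats(gsm, {"a": "G1", "b": "G1", "c": "G1"})
        assert stats[0].mean_within_gs == pytest.approx(0.92)
        assert stats[0].min_within_gs == pytest.approx(0.90)
        assert between is None

    def test_singleton_flagged_and_between_min(self):
        gs = [[1.0, 0.9, 0.2],
              [0.9, 1.0, 0.4],
              [0.2, 0.4, 1.0]]
        gsm = gsm_from(list("abc"), gs)
        stats, between = pedigree_stats(gsm, {"a": "G1", "b": "G1", "c": "G2"})
        singleton = next(s for s in stats if s.label == "G2")
        assert singleton.mean_within_gs is None
        assert between == pytest.approx(0.2)  # global min over cross pairs
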