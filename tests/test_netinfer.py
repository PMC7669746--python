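import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stagenet.core import ExpressionMatrix, MIRankedEdgeList, StagenetError
from stagenet.netinfer import (
    MIEstimatorConfig,
    dpi_prune,
    equal_frequency_bins,
    mi_from_joint,
    mi_matrix,
    mutual_information,
    top_n,
)


def direct_mi_bits(table):
    """Independent oracle: literal double loop over the joint table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    total = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            pij = table[i, j] / n
            if pij > 0:
                pi = table[i, :].sum() / n
                pj = table[:, j].sum() / n
                total += pij * math.log2(pij / (pi * pj))
    return total


class TestJointMI:
    def test_perfect_two_symbol_dependence_is_one_bit(self):
        assert mi_from_joint([[2, 0], [0, 2]]) == pytest.approx(1.0, abs=1e-12)

    def test_independence_is_zero_bits(self):
        assert mi_from_joint([[1, 1], [1, 1]]) == pytest.approx(0.0, abs=1e-12)

    def test_printed_worked_table(self):
        assert mi_from_joint([[3, 1], [1, 3]]) == pytest.approx(0.18872, abs=5e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_direct_evaluation_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        shape = rng.integers(2, 6, size=2)
        table = rng.integers(0, 7, size=shape)
        if table.sum() == 0:
            table[0, 0] = 1
        assert mi_from_joint(table) == pytest.approx(
            max(direct_mi_bits(table), 0.0), abs=1e-12
        )


class TestMutualInformation:
    def test_symmetry_exact(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_constant_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(np.ones(20), np.arange(20.0)) == 0.0

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(StagenetError, match="mismatch"):
            mutual_information(np.ones(9), np.ones(10))
        with pytest.raises(StagenetError, match=">= 8"):
            mutual_information(np.arange(5.0), np.arange(5.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rank_invariance_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = rng.normal(size=40) + 0.5 * x
        base = mutual_information(x, y)
        assert mutual_information(np.exp(x), y) == base
        assert mutual_information(x, y ** 3 + 2 * y) == base

    def test_independent_vectors_near_zero_self_mi_maximal(self):
        # The plug-in estimate carries an upward bias of roughly
        # (B-1)^2 / (2 n ln 2) bits, so near-zero MI on independent
        # data needs the per-cell occupancy n/B^2 to be large; at B=8,
        # n=1000 the plug-in lands under 0.05 bits and Miller-Madow
        # essentially removes what remains.
        rng = np.random.default_rng(1)
        plugin_cfg = MIEstimatorConfig(n_bins=8)
        mm_cfg = MIEstimatorConfig(n_bins=8, estimator="miller_madow")
        plug, mm = [], []
        for _ in range(20):
            x, y = rng.normal(size=1000), rng.normal(size=1000)
            plug.append(mutual_information(x, y, plugin_cfg))
            mm.append(mutual_information(x, y, mm_cfg))
        assert np.mean(plug) < 0.05
        assert np.mean(mm) < 0.01
        x = rng.normal(size=200)
        others = [rng.normal(size=200) for _ in range(5)]
        self_mi = mutual_information(x, x)
        assert all(self_mi > mutual_information(x, o) for o in others)

    def test_miller_madow_corrects_downward_on_independent_data(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=60), rng.normal(size=60)
        plug = mutual_information(x, y, MIEstimatorConfig(estimator="plugin"))
        mm = mutual_information(x, y, MIEstimatorConfig(estimator="miller_madow"))
        assert mm < plug


class TestEqualFrequencyBins:
    def test_balanced_deterministic_partition(self):
        bins = equal_frequency_bins(np.array([5.0, 1.0, 3.0, 2.0, 4.0, 0.0]), 3)
        assert sorted(np.bincount(bins)) == [2, 2, 2]
        # ties broken by original index: stable order
        tied = equal_frequency_bins(np.zeros(6), 3)
        np.testing.assert_array_equal(tied, [0, 0, 1, 1, 2, 2])


class TestMiMatrix:
    def test_three_genes_give_three_ranked_edges(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(rng.normal(size=(3, 20)), ["a", "b", "c"], [f"s{i}" for i in range(20)])
        edges = mi_matrix(m)
        assert len(edges) == 3
        mis = [w for _, _, w in edges]
        assert mis == sorted(mis, reverse=True)

    def test_consistent_with_pairwise_calls(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 24))
        vals[3] = 7.0  # constant gene: zero MI by definition
        m = ExpressionMatrix(vals, [f"g{i}" for i in range(5)], [f"s{i}" for i in range(24)])
        edges = {(a, b): w for a, b, w in mi_matrix(m)}
        cfg = MIEstimatorConfig()
        for i, j in itertools.combinations(range(5), 2):
            if i == 3 or j == 3:
                expected = 0.0
            else:
                expected = mutual_information(vals[i], vals[j], cfg)
            assert edges[(f"g{i}", f"g{j}")] == pytest.approx(expected, abs=1e-12)

    def test_sample_subset_is_respected(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(3, 30))
        m = ExpressionMatrix(vals, ["a", "b", "c"], [f"s{i}" for i in range(30)])
        sub = [f"s{i}" for i in range(10)]
        edges = {(a, b): w for a, b, w in mi_matrix(m, samples=sub)}
        direct = mutual_information(vals[0, :10], vals[1, :10])
        assert edges[("a", "b")] == pytest.approx(direct)


def brute_force_dpi(edges, tolerance=0.0):
    """Oracle: enumerate all node triples, mark weakest edge per triangle."""
    mi = {(a, b): w for a, b, w in edges}
    nodes = sorted({n for a, b, _ in edges for n in (a, b)})
    doomed = set()
    for trio in itertools.combinations(nodes, 3):
        pairs = [tuple(sorted(p)) for p in itertools.combinations(trio, 2)]
        if not all(p in mi for p in pairs):
            continue
        ws = sorted(pairs, key=lambda p: mi[p])
        if mi[ws[0]] < (1 - tolerance) * mi[ws[1]]:
            doomed.add(ws[0])
    return MIRankedEdgeList([e for e in edges.edges if (e[0], e[1]) not in doomed])


class TestDpi:
    def test_weakest_triangle_edge_removed(self):
        edges = MIRankedEdgeList.from_records(
            [("A", "B", 0.5), ("B", "C", 0.4), ("A", "C", 0.1)]
        )
        pruned = dpi_prune(edges)
        assert pruned.pairs() == {("A", "B"), ("B", "C")}

    def test_edge_outside_any_triangle_kept(self):
        edges = MIRankedEdgeList.from_records(
            [("A", "B", 0.5), ("B", "C", 0.4), ("A", "C", 0.1), ("C", "D", 0.01)]
        )
        assert ("C", "D") in dpi_prune(edges).pairs()

    def test_tied_minimum_not_removed_at_zero_tolerance(self):
        edges = MIRankedEdgeList.from_records(
            [("A", "B", 0.4), ("B", "C", 0.4), ("A", "C", 0.4)]
        )
        assert len(dpi_prune(edges)) == 3

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(8)]
        records = [
            (a, b, float(rng.uniform(0.01, 1.0)))
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.55
        ]
        edges = MIRankedEdgeList.from_records(records)
        tol = float(rng.choice([0.0, 0.1, 0.3]))
        assert dpi_prune(edges, tol).edges == brute_force_dpi(edges, tol).edges


class TestTopN:
    def test_nested_prefix_property(self):
        rng = np.random.default_rng(3)
        records = [
            (f"a{i}", f"b{i}", float(rng.uniform())) for i in range(50)
        ]
        edges = MIRankedEdgeList.from_records(records)
        top10 = top_n(edges, 10)
        top25 = top_n(edges, 25)
        assert top10.pairs() <= top25.pairs()
        assert top25.edges[:10] == top10.edges
        assert top_n(edges, 1).edges[0] == edges.edges[0]
        assert len(top_n(edges, 10_000)) == 50
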