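"""Module miners against worked matrices and brute-force oracles."""

import numpy as np
import pytest

from mtbkit import InteractionNetwork, MinerParams
from mtbkit.core import (MTB, dedup_similar, find_components_L,
                         find_dense_Lgen, find_dense_one_side, find_exact_R,
                         find_maximal_Rgen,
                         find_maximal_row_or_col_restricted, find_mtbs,
                         load_mtbs, save_mtbs, submatrix_density, summarize)

import oracles


def found_as_sets(mtbs):
    return {(frozenset(b.rows), frozenset(b.cols)) for b in mtbs}


class TestSubmatrixDensity:
    def test_partial_full_and_empty(self, matrix_c):
        # {g1..g4} x {m1..m3} holds 10 of 12 possible interactions
        assert submatrix_density(matrix_c, range(4), range(3)) \
            == pytest.approx(10 / 12)
        assert submatrix_density(matrix_c, range(3), [0, 1]) == 1.0
        assert submatrix_density(matrix_c, [3], [0, 1]) == 0.0

    def test_out_of_range_raises(self, matrix_c):
        with pytest.raises(IndexError):
            submatrix_density(matrix_c, [0, 99], [0])


class TestExactFinders:
    def test_matrix_a_exact_R(self, matrix_a, params, as_ids):
        found = find_exact_R(matrix_a, params)
        assert [as_ids(b, matrix_a) for b in found] \
            == [(("g1", "g2"), ("m1", "m2"))]
        assert found[0].density == 1.0

    def test_all_zeros_and_all_ones(self, params):
        zeros = InteractionNetwork(["g1", "g2"], ["m1", "m2"],
                                   np.zeros((2, 2)))
        assert find_exact_R(zeros, params) == []
        ones = InteractionNetwork([f"g{i}" for i in range(3)],
                                  [f"m{j}" for j in range(4)],
                                  np.ones((3, 4)))
        found = find_exact_R(ones, params)
        assert found_as_sets(found) == {(frozenset(range(3)),
                                         frozenset(range(4)))}

    def test_matrix_a_one_side_restricted(self, matrix_a, params, as_ids):
        rmi = find_maximal_row_or_col_restricted(matrix_a, "mrnas", params)
        assert [as_ids(b, matrix_a) for b in rmi] \
            == [(("g1", "g2"), ("m1", "m2"))]
        # without the size filter the maximal list has all three groups
        loose = MinerParams(min_mrnas=1, min_mirnas=1)
        rmi_all = find_maximal_row_or_col_restricted(matrix_a, "mrnas", loose)
        assert found_as_sets(rmi_all) == {
            (frozenset({0, 1}), frozenset({0, 1})),
            (frozenset({2, 3}), frozenset({2})),
            (frozenset({3, 4}), frozenset({3}))}
        rm = find_maximal_row_or_col_restricted(matrix_a, "mirnas", params)
        assert [as_ids(b, matrix_a) for b in rm] \
            == [(("g1", "g2"), ("m1", "m2"))]

    def test_distinct_signatures_give_no_groups(self, matrix_b, params):
        # all seven row signatures differ, so no 2-row Rm group exists
        assert find_maximal_row_or_col_restricted(matrix_b, "mirnas",
                                                  params) == []

    def test_matrix_b_maximal_bicliques(self, matrix_b, params, as_ids):
        found = find_maximal_Rgen(matrix_b, params)
        # rows named g1..g7 carry signatures 001..111 over columns m1..m3
        expected = {
            (("g6", "g7"), ("m1", "m2")),
            (("g5", "g7"), ("m1", "m3")),
            (("g3", "g7"), ("m2", "m3")),
        }
        assert {as_ids(b, matrix_b) for b in found} == expected
        assert all(b.density == 1.0 for b in found)

    def test_matrix_a_rgen(self, matrix_a, params, as_ids):
        found = find_maximal_Rgen(matrix_a, params)
        assert [as_ids(b, matrix_a) for b in found] \
            == [(("g1", "g2"), ("m1", "m2"))]

    def test_candidate_cap(self):
        ones = InteractionNetwork([f"g{i}" for i in range(6)],
                                  [f"m{j}" for j in range(6)],
                                  np.ones((6, 6)))
        with pytest.raises(RuntimeError, match="cap"):
            find_maximal_Rgen(ones, MinerParams(max_candidates=3))

    def test_matrix_a_components(self, matrix_a, params, as_ids):
        found = find_components_L(matrix_a, params)
        assert {as_ids(b, matrix_a) for b in found} == {
            (("g1", "g2"), ("m1", "m2")),
            (("g3", "g4", "g5"), ("m3", "m4"))}
        dens = {as_ids(b, matrix_a): b.density for b in found}
        assert dens[(("g3", "g4", "g5"), ("m3", "m4"))] \
            == pytest.approx(4 / 6)


class TestGreedyGrowth:
    def test_matrix_c_lmi_grows_to_full_block(self, matrix_c, params, as_ids):
        found = find_dense_one_side(matrix_c, "mrnas", params)
        assert [as_ids(b, matrix_c) for b in found] \
            == [(("g1", "g2", "g3", "g4"), ("m1", "m2", "m3"))]
        assert found[0].density == pytest.approx(10 / 12)

    def test_matrix_c_theta_one_keeps_seeds(self, matrix_c, as_ids):
        found = find_dense_one_side(matrix_c, "mrnas",
                                    MinerParams(density_threshold=1.0))
        assert [as_ids(b, matrix_c) for b in found] \
            == [(("g1", "g2", "g3"), ("m1", "m2"))]

    def test_matrix_a_lmi(self, matrix_a, params, as_ids):
        found = find_dense_one_side(matrix_a, "mrnas", params)
        by_ids = {as_ids(b, matrix_a): b for b in found}
        # the exact module is untouched: no candidate column has any edge
        # to its rows
        assert (("g1", "g2"), ("m1", "m2")) in by_ids
        assert by_ids[(("g1", "g2"), ("m1", "m2"))].density == 1.0
        # the m3/m4 groups coalesce into the other component at density 4/6
        assert by_ids[(("g3", "g4", "g5"), ("m3", "m4"))].density \
            == pytest.approx(4 / 6)

    def test_matrix_a_lgen_unchanged(self, matrix_a, params, as_ids):
        found = find_dense_Lgen(matrix_a, params)
        assert [as_ids(b, matrix_a) for b in found] \
            == [(("g1", "g2"), ("m1", "m2"))]

    def test_matrix_c_lgen(self, matrix_c, params, as_ids):
        found = find_dense_Lgen(matrix_c, params)
        assert [as_ids(b, matrix_c) for b in found] \
            == [(("g1", "g2", "g3", "g4"), ("m1", "m2", "m3"))]

    def test_grown_modules_respect_threshold_and_connectivity(self):
        rng = np.random.default_rng(7)
        import oracles as orc
        for _ in range(10):
            adj = orc.random_binary_matrix(rng, 8, 8, 0.4)
            net = InteractionNetwork([f"g{i}" for i in range(8)],
                                     [f"m{j}" for j in range(8)], adj)
            for finder in (lambda n: find_dense_one_side(n, "mrnas"),
                           lambda n: find_dense_one_side(n, "mirnas"),
                           find_dense_Lgen):
                for b in finder(net):
                    assert b.density >= 0.3
                    comp = orc.enumerate_components(
                        adj[np.ix_(sorted(b.rows), sorted(b.cols))])
                    assert len(comp) == 1  # induced subgraph connected


class TestDedup:
    def mk(self, rows, cols, density=1.0):
        return MTB(frozenset(rows), frozenset(cols), "Rgen", density)

    def test_identical_disjoint_and_threshold(self):
        a, b = self.mk({0, 1}, {0, 1}), self.mk({0, 1}, {0, 1})
        assert dedup_similar([a, b], 0.9, n_rows=5) == [a]
        c = self.mk({2, 3}, {2, 3})
        assert len(dedup_similar([a, c], 0.9, n_rows=5)) == 2
        # combined members share 3 of 7 -> Jaccard 3/7 > 0.4: smaller dropped
        big = self.mk({0, 1, 2}, {0, 1})
        small = self.mk({0, 1}, {0})
        assert dedup_similar([big, small], 0.4, n_rows=5) == [big]
        assert len(dedup_similar([big, small], 0.9, n_rows=5)) == 2


class TestSummarize:
    def test_counts_and_means(self):
        mk = lambda r, c: MTB(frozenset(range(r)), frozenset(range(c)),
                              "L", 0.5)
        s = summarize([mk(2, 2), mk(4, 3)])
        assert s == {"count": 2, "mean_mrnas": 3.0, "mean_mirnas": 2.5}
        assert summarize([]) == {"count": 0, "mean_mrnas": None,
                                 "mean_mirnas": None}
        assert summarize([mk(5, 2)]) == {"count": 1, "mean_mrnas": 5.0,
                                         "mean_mirnas": 2.0}


def _predicates(adj, rows, cols):
    """Figure-level predicates: biclique, row/col closure, connectedness."""
    sub = adj[np.ix_(sorted(rows), sorted(cols))]
    other_cols = sorted(set(range(adj.shape[1])) - cols)
    other_rows = sorted(set(range(adj.shape[0])) - rows)
    return {
        "all_ones": bool(sub.all()),
        "rows_closed": not other_cols
            or not adj[np.ix_(sorted(rows), other_cols)].any(),
        "cols_closed": not other_rows
            or not adj[np.ix_(other_rows, sorted(cols))].any(),
        "connected": len(oracles.enumerate_components(sub)) == 1,
    }


class TestOracleEquivalenceAndInvariants:
    """Random-matrix checks of the complete-enumeration finders."""

    @pytest.mark.parametrize("seed", [11, 23])
    def test_finders_match_brute_force(self, seed, params):
        for adj in oracles.oracle_matrix_stream(seed, n_matrices=20):
            net = InteractionNetwork(
                [f"g{i}" for i in range(adj.shape[0])],
                [f"m{j}" for j in range(adj.shape[1])], adj)
            assert found_as_sets(find_exact_R(net, params)) \
                == oracles.size_filtered(oracles.enumerate_R(adj))
            assert found_as_sets(
                find_maximal_row_or_col_restricted(net, "mrnas", params)) \
                == oracles.size_filtered(oracles.enumerate_maximal_Rmi(adj))
            assert found_as_sets(
                find_maximal_row_or_col_restricted(net, "mirnas", params)) \
                == oracles.size_filtered(oracles.enumerate_maximal_Rm(adj))
            assert found_as_sets(find_maximal_Rgen(net, params)) \
                == oracles.size_filtered(
                    oracles.enumerate_maximal_bicliques(adj))
            assert found_as_sets(find_components_L(net, params)) \
                == oracles.size_filtered(oracles.enumerate_components(adj))

    def test_count_bounds_and_lattice(self, params):
        loose = MinerParams(min_mrnas=1, min_mirnas=1)
        for adj in oracles.oracle_matrix_stream(99, n_matrices=20):
            net = InteractionNetwork(
                [f"g{i}" for i in range(adj.shape[0])],
                [f"m{j}" for j in range(adj.shape[1])], adj)
            n_r, n_c = adj.shape
            assert len(find_exact_R(net, loose)) <= min(n_r, n_c)
            assert len(find_maximal_row_or_col_restricted(
                net, "mrnas", loose)) <= n_c
            assert len(find_maximal_row_or_col_restricted(
                net, "mirnas", loose)) <= n_r
            assert len(find_components_L(net, loose)) <= min(n_r, n_c)
            # every exact module satisfies all other type predicates
            for b in find_exact_R(net, loose):
                preds = _predicates(adj, set(b.rows), set(b.cols))
                assert all(preds.values())
            # every maximal biclique satisfies the loose-general predicate
            for b in find_maximal_Rgen(net, loose):
                preds = _predicates(adj, set(b.rows), set(b.cols))
                assert preds["all_ones"] and preds["connected"]

    def test_determinism(self, params):
        adj = next(oracles.oracle_matrix_stream(5, n_matrices=1))
        net = InteractionNetwork([f"g{i}" for i in range(adj.shape[0])],
                                 [f"m{j}" for j in range(adj.shape[1])], adj)
        for mtb_type in ("R", "Rmi", "Rm", "Rgen", "L", "Lmi", "Lm", "Lgen"):
            first = find_mtbs(net, mtb_type, params)
            second = find_mtbs(net, mtb_type, params)
            assert first == second


class TestDispatchAndIO:
    def test_unknown_type(self, matrix_a, params):
        with pytest.raises(ValueError, match="unknown MTB type"):
            find_mtbs(matrix_a, "Rx", params)

    def test_save_load_roundtrip(self, matrix_a, params, tmp_path):
        mtbs = find_mtbs(matrix_a, "L", params)
        path = tmp_path / "mtbs.json"
        save_mtbs(mtbs, matrix_a, path)
        assert load_mtbs(path, matrix_a) == mtbs
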