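"""Fraction statistics, backgrounds, Wilcoxon comparisons and workflows."""

import itertools
import math

import numpy as np
import pytest

from mtbkit import (ExpressionMatrix, InteractionNetwork, MinerParams,
                    SyntheticSpec, ThresholdGrid, buffering_workflow,
                    evaluate_workflow, find_dense_Lgen, fraction_beyond,
                    generate_all, mtb_pair_fractions, outside_background,
                    per_mtb_mean_d, rank_top_bottom, sample_random_background,
                    wilcoxon_one_sided)
from mtbkit.core import MTB
from mtbkit.evalstats import GridSpec, grid_comparison
from mtbkit.expression import pearson


class TestFractionBeyond:
    def test_directions_and_nan(self):
        assert fraction_beyond([-0.5, -0.05, -0.3], -0.1, "below") \
            == pytest.approx(2 / 3)
        assert fraction_beyond([0.2, 0.05], 0.1, "above") == 0.5
        assert math.isnan(fraction_beyond([np.nan, np.nan], 0.1, "above"))
        # strict inequality: values equal to t do not count
        assert fraction_beyond([-0.1, -0.2], -0.1, "below") == 0.5


class TestThresholdGrid:
    def test_defaults_match_workflow_grids(self):
        assert ThresholdGrid.anticorrelation().values \
            == tuple(pytest.approx(-k / 10) for k in range(1, 8))
        assert ThresholdGrid.positive().values \
            == tuple(pytest.approx(k / 10) for k in range(1, 8))
        with pytest.raises(ValueError):
            ThresholdGrid([])


def make_expr(ids, values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(ids, [f"s{i}" for i in range(values.shape[1])],
                            values - values.min() + 0.1)


@pytest.fixture
def tiny_dataset():
    """2 miRNAs x 3 mRNAs, fully connected, with known correlations."""
    net = InteractionNetwork.from_edges(
        [(m, g) for m in ("m1", "m2") for g in ("g1", "g2", "g3")])
    e_mi = make_expr(["m1", "m2"], [[1, 2, 3, 4], [4, 3, 2, 1]])
    e_m = make_expr(["g1", "g2", "g3"],
                    [[4, 3, 2, 1],    # anti-correlated with m1
                     [1, 2, 3, 4],    # correlated with m1
                     [4, 3, 2, 1]])
    mtb = MTB(frozenset(range(3)), frozenset(range(2)), "Lgen", 1.0)
    return net, e_mi, e_m, [mtb]


class TestPairFractions:
    def test_mirna_mrna_fraction(self, tiny_dataset):
        net, e_mi, e_m, mtbs = tiny_dataset
        # pair correlations: m1 vs (g1,g2,g3) = (-1,+1,-1); m2 mirrored
        fr = mtb_pair_fractions(mtbs, net, e_mi, e_m, -0.2, "mirna_mrna")
        # of the 6 pairs, 3 are perfectly negative and 3 perfectly positive
        assert fr.tolist() == [0.5]

    def test_mrna_mrna_needs_three_mrnas(self, tiny_dataset):
        net, e_mi, e_m, _ = tiny_dataset
        small = MTB(frozenset({0, 1}), frozenset({0, 1}), "Lgen", 1.0)
        big = MTB(frozenset(range(3)), frozenset(range(2)), "Lgen", 1.0)
        fr = mtb_pair_fractions([small, big], net, e_mi, e_m, 0.1,
                                "mrna_mrna")
        assert fr.size == 1  # the 2-mRNA module is excluded
        # pairs (g1,g2)=-1, (g1,g3)=+1, (g2,g3)=-1
        assert fr.tolist() == [pytest.approx(1 / 3)]


class TestRandomBackground:
    def test_reproducible_and_sizes(self, tiny_dataset):
        net, e_mi, e_m, mtbs = tiny_dataset
        kw = dict(mirna_pool=net.mirna_ids, mrna_pool=net.mrna_ids,
                  n_sets=25, seed=7, expr_mirna=e_mi, expr_mrna=e_m,
                  t=-0.2, pair_kind="mirna_mrna")
        a = sample_random_background(mtbs, **kw)
        b = sample_random_background(mtbs, **kw)
        assert np.array_equal(a, b) and a.size == 25
        assert sample_random_background(mtbs, net.mirna_ids, net.mrna_ids,
                                        0, 7, e_mi, e_m, -0.2).size == 0

    def test_pool_too_small(self, tiny_dataset):
        net, e_mi, e_m, mtbs = tiny_dataset
        with pytest.raises(ValueError, match="pool"):
            sample_random_background(mtbs, ["m1"], net.mrna_ids, 5, 0,
                                     e_mi, e_m, -0.2)


class TestOutsideBackground:
    def test_saturated_module_gives_nan(self, matrix_c):
        e_mi = make_expr(["m1", "m2", "m3"], np.arange(12).reshape(3, 4))
        e_m = make_expr(["g1", "g2", "g3", "g4"],
                        np.arange(16).reshape(4, 4))
        mtb = MTB(frozenset(range(4)), frozenset(range(3)), "Lgen", 10 / 12)
        out = outside_background(matrix_c, [mtb], "mirna_targets",
                                 e_mi, e_m, -0.1)
        assert math.isnan(out[0])

    def test_outside_pair_construction(self, matrix_a):
        # extend matrix A with edge m1-g3: the module's only outside pair
        adj = matrix_a.adjacency.copy()
        adj[matrix_a.mrna_index()["g3"], matrix_a.mirna_index()["m1"]] = 1
        net = InteractionNetwork(matrix_a.mrna_ids, matrix_a.mirna_ids, adj)
        rng = np.random.default_rng(0)
        e_mi = make_expr(net.mirna_ids, rng.random((4, 5)))
        e_m = make_expr(net.mrna_ids, rng.random((5, 5)))
        mtb = MTB(frozenset({0, 1}), frozenset({0, 1}), "Rgen", 1.0)
        expected_r = pearson(e_mi.profile("m1"), e_m.profile("g3"))
        for t, want in ((expected_r + 0.01, 1.0), (expected_r - 0.01, 0.0)):
            out = outside_background(net, [mtb], "mirna_targets",
                                     e_mi, e_m, t)
            assert out.tolist() == [want]


class TestWilcoxon:
    def test_exact_complete_separation(self):
        assert wilcoxon_one_sided([0.9, 0.8, 0.7], [0.1, 0.2, 0.3],
                                  "a_greater") == pytest.approx(1 / 20)

    def test_identical_samples(self):
        assert wilcoxon_one_sided([1, 2, 3], [1, 2, 3], "a_greater") >= 0.5

    def test_floor(self):
        a = np.ones(400)
        b = np.zeros(400)
        assert wilcoxon_one_sided(a, b, "a_greater") == 1e-16

    def test_swapped_samples_mirrored_alternative(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(8), rng.random(15)
        assert wilcoxon_one_sided(a, b, "a_greater") \
            == pytest.approx(wilcoxon_one_sided(b, a, "a_less"))

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.permutation(np.arange(12.0))[:5]
            b = np.setdiff1d(np.arange(12.0), a)[:4]
            got = wilcoxon_one_sided(a, b, "a_greater")
            # enumerate all rank splits of the combined sample
            combined = np.concatenate([a, b])
            ranks = combined.argsort().argsort() + 1
            obs = ranks[:a.size].sum()
            total = list(
                itertools.combinations(range(1, combined.size + 1), a.size))
            count = sum(sum(c) >= obs for c in total)
            assert got == pytest.approx(count / len(total))

    def test_empty_after_nan_removal(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([np.nan], [1.0], "a_greater")


class TestWorkflows:
    def test_grid_cardinality(self, tiny_dataset):
        net, e_mi, e_m, mtbs = tiny_dataset
        res = evaluate_workflow(mtbs, net, e_mi, e_m,
                                grid=ThresholdGrid.anticorrelation(),
                                background="random_sets", n_random=20,
                                seed=3)
        assert len(res) == 7
        assert all(1e-16 <= r.p_value <= 1.0 for r in res)

    def test_planted_anticorrelation_is_detected(self):
        # modules mined from replicate planted simulations carry miRNA-mRNA
        # anti-correlation well beyond size-matched random sets
        fg, bg = [], []
        for k in range(10):
            spec = SyntheticSpec(effect_buffer=0.0, seed=1000 + k)
            net, planted, e_mi, e_m, _ = generate_all(spec)
            mtbs = find_dense_Lgen(net, MinerParams())
            fg.extend(mtb_pair_fractions(mtbs, net, e_mi, e_m, -0.1,
                                         "mirna_mrna"))
            bg.extend(sample_random_background(
                mtbs, net.mirna_ids, net.mrna_ids, 100, 1000 + k,
                e_mi, e_m, -0.1))
        assert wilcoxon_one_sided(fg, bg, "a_greater") < 0.01

    def test_buffering_workflow_shapes(self):
        spec = SyntheticSpec(seed=3)
        net, planted, e_mi, e_m, _ = generate_all(spec)
        res = buffering_workflow(planted, net, e_mi, e_m,
                                 grid=ThresholdGrid([-0.1, -0.2]))
        assert len(res) == 2
        assert all(r.background_kind == "outside_triples" for r in res)

    def test_external_module_list_as_background(self, tiny_dataset):
        net, e_mi, e_m, mtbs = tiny_dataset
        other = [MTB(frozenset({0, 1}), frozenset({0, 1}), "Lgen", 1.0)]
        res = evaluate_workflow(mtbs, net, e_mi, e_m,
                                grid=ThresholdGrid([-0.1]),
                                background_mtbs=other)
        assert res[0].background_kind == "mrm_list"


class TestRanking:
    def mk(self, i):
        return MTB(frozenset({i, i + 1}), frozenset({0, 1}), "Lgen", 1.0)

    def test_extremes_full_and_clip(self):
        mtbs = [self.mk(i) for i in range(4)]
        mean_d = [-0.5, -0.1, 0.2, 0.4]
        top, bottom = rank_top_bottom(mtbs, mean_d, 1)
        assert top == [mtbs[0]] and bottom == [mtbs[3]]
        top, bottom = rank_top_bottom(mtbs, mean_d, 4)
        assert top == mtbs and bottom == mtbs[::-1]
        with pytest.warns(UserWarning, match="clipped"):
            top, _ = rank_top_bottom(mtbs, mean_d, 10)
        assert len(top) == 4

    def test_boundary_ties_broken_deterministically(self):
        mtbs = [self.mk(i) for i in range(3)]
        top, _ = rank_top_bottom(mtbs, [0.1, 0.1, 0.5], 1)
        assert top == [min(mtbs[:2], key=lambda b: b.sort_key())]


class TestGridComparison:
    def test_single_network_grid(self):
        spec = SyntheticSpec(seed=5)
        net, planted, e_mi, e_m, _ = generate_all(spec)
        gspec = GridSpec(x_values=(2,), t_values=tuple(np.arange(1, 8) / 10),
                         networks=("net",))
        comp = grid_comparison({"net": (planted, net, e_mi, e_m)}, gspec)
        assert comp.n_settings == 7
        assert len(comp.rows) == 7
        assert 0 <= comp.n_top_wins <= 7

    def test_full_grid_cardinality(self):
        gspec = GridSpec(networks=("a", "b", "c", "d"))
        assert gspec.n_settings == 112
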