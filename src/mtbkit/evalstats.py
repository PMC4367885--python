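"""Evaluation workflows for mined MTBs.

The central unit of comparison is the *fraction-beyond-threshold* statistic:
for each module, the proportion of pairwise expression correlations (or
buffering d values) beyond a cutoff t.  The vector of per-module fractions is
compared against a background vector with a one-sided Wilcoxon rank-sum test.
Three background constructions are provided: random miRNA/mRNA sets matching
the module size distribution, out-of-module counterparts built from the
network (a module's miRNAs with their other targets; mRNA pairs sharing a
targeting miRNA but never co-occurring in a module; buffering triples with
the regulator inside and both targets outside the module), and an externally
supplied module list.

Reported p-values are floored at 1e-16 and are not corrected for multiple
testing; the workflows are meant for comparing parameter settings, not for
declaring individual modules significant.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import scipy.stats

from .core import MTB
from .expression import d_statistic, pearson
from .netio import ExpressionMatrix, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "P_FLOOR",
    "ThresholdGrid",
    "EvalResult",
    "GridSpec",
    "fraction_beyond",
    "mtb_pair_fractions",
    "sample_random_background",
    "outside_background",
    "wilcoxon_one_sided",
    "evaluate_workflow",
    "buffering_workflow",
    "per_mtb_mean_d",
    "rank_top_bottom",
    "grid_comparison",
]

#: reporting floor for p-values
P_FLOOR = 1e-16


@dataclass(frozen=True)
class ThresholdGrid:
    """Correlation thresholds t, sorted by increasing magnitude."""

    values: tuple

    def __init__(self, values: Iterable[float]):
        vals = tuple(sorted((float(v) for v in values), key=abs))
        if not vals:
            raise ValueError("threshold grid must be non-empty")
        object.__setattr__(self, "values", vals)

    @classmethod
    def anticorrelation(cls) -> "ThresholdGrid":
        """Default grid for negative correlations: -0.1 .. -0.7 step -0.1."""
        return cls(-np.arange(1, 8) / 10)

    @classmethod
    def positive(cls) -> "ThresholdGrid":
        """Default grid for positive correlations: 0.1 .. 0.7 step 0.1."""
        return cls(np.arange(1, 8) / 10)


@dataclass
class EvalResult:
    """One workflow comparison at a single threshold."""

    mtb_type: str
    t: float
    mtb_fractions: np.ndarray
    background_fractions: np.ndarray
    p_value: float
    background_kind: str

    def __post_init__(self) -> None:
        self.mtb_fractions = np.asarray(self.mtb_fractions, dtype=float)
        self.background_fractions = np.asarray(self.background_fractions,
                                               dtype=float)
        if not (P_FLOOR <= self.p_value <= 1.0):
            raise ValueError("p-value outside [1e-16, 1]")

    @property
    def n_fg(self) -> int:
        return int(np.sum(~np.isnan(self.mtb_fractions)))

    @property
    def n_bg(self) -> int:
        return int(np.sum(~np.isnan(self.background_fractions)))


@dataclass(frozen=True)
class GridSpec:
    """The (network, x, t) grid of the top-vs-bottom buffering comparison."""

    x_values: tuple = (100, 200, 500, 1000)
    t_values: tuple = tuple(np.arange(1, 8) / 10)
    networks: tuple = ()

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.x_values) or not self.x_values:
            raise ValueError("x values must be positive")
        if not self.t_values:
            raise ValueError("t values must be non-empty")

    @property
    def n_settings(self) -> int:
        return len(self.networks) * len(self.x_values) * len(self.t_values)


def fraction_beyond(values, t: float,
                    direction: Literal["below", "above"]) -> float:
    """Fraction of non-NaN values strictly beyond t; NaN if none remain."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan")
    if direction == "below":
        return float(np.mean(values < t))
    if direction == "above":
        return float(np.mean(values > t))
    raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")


def _profiles(expr: ExpressionMatrix,
              ids: Sequence[str]) -> dict[str, np.ndarray]:
    index = expr.index()
    return {i: expr.values[index[i]] for i in ids if i in index}


def _mtb_pair_values(
    mtb: MTB,
    network: InteractionNetwork,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    pair_kind: str,
) -> np.ndarray:
    """Pearson correlations of all within-module pairs of the given kind."""
    mrnas = [network.mrna_ids[i] for i in sorted(mtb.rows)]
    mirnas = [network.mirna_ids[j] for j in sorted(mtb.cols)]
    gprof = _profiles(expr_mrna, mrnas)
    skipped = 0
    vals: list[float] = []
    if pair_kind == "mirna_mrna":
        mprof = _profiles(expr_mirna, mirnas)
        for m in mirnas:
            for g in mrnas:
                if m not in mprof or g not in gprof:
                    skipped += 1
                    continue
                vals.append(pearson(mprof[m], gprof[g]))
    elif pair_kind == "mrna_mrna":
        for g1, g2 in itertools.combinations(mrnas, 2):
            if g1 not in gprof or g2 not in gprof:
                skipped += 1
                continue
            vals.append(pearson(gprof[g1], gprof[g2]))
    else:
        raise ValueError(f"unknown pair_kind {pair_kind!r}")
    if skipped:
        logger.info("skipped %d pairs with missing expression", skipped)
    return np.asarray(vals, dtype=float)


#: minimum mRNA count for the mRNA-mRNA positive-correlation analysis,
#: so every module contributes more than a single correlation value
MIN_MRNAS_FOR_PAIRS = 3


def _eligible(mtbs: Sequence[MTB], pair_kind: str) -> list[MTB]:
    if pair_kind == "mrna_mrna":
        return [b for b in mtbs if b.n_mrnas >= MIN_MRNAS_FOR_PAIRS]
    return list(mtbs)


def mtb_pair_fractions(
    mtbs: Sequence[MTB],
    network: InteractionNetwork,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    t: float,
    pair_kind: Literal["mirna_mrna", "mrna_mrna"] = "mirna_mrna",
) -> np.ndarray:
    """Per-module fraction of pair correlations beyond t.

    miRNA-mRNA pairs are counted below t (anti-correlation); mRNA-mRNA pairs
    above t (positive correlation), with modules of fewer than three mRNAs
    excluded from the latter.
    """
    direction = "below" if pair_kind == "mirna_mrna" else "above"
    return np.array([
        fraction_beyond(
            _mtb_pair_values(b, network, expr_mirna, expr_mrna, pair_kind),
            t, direction)
        for b in _eligible(mtbs, pair_kind)])


def _random_set_values(
    mtbs: Sequence[MTB],
    mirna_pool: Sequence[str],
    mrna_pool: Sequence[str],
    n_sets: int,
    seed: int,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    pair_kind: str,
) -> list[np.ndarray]:
    """Correlation values of random modules matching the MTB size list."""
    eligible = _eligible(mtbs, pair_kind)
    if not eligible:
        raise ValueError("no modules to match sizes against")
    sizes = [(b.n_mrnas, b.n_mirnas) for b in eligible]
    if max(s[0] for s in sizes) > len(mrna_pool) \
            or max(s[1] for s in sizes) > len(mirna_pool):
        raise ValueError("entity pool smaller than the largest module side")
    rng = np.random.default_rng(seed)
    mirna_pool = sorted(mirna_pool)
    mrna_pool = sorted(mrna_pool)
    gprof = _profiles(expr_mrna, mrna_pool)
    mprof = _profiles(expr_mirna, mirna_pool)
    out = []
    for _ in range(n_sets):
        n_g, n_m = sizes[rng.integers(len(sizes))]
        genes = list(rng.choice(mrna_pool, size=n_g, replace=False))
        mirnas = list(rng.choice(mirna_pool, size=n_m, replace=False))
        vals: list[float] = []
        if pair_kind == "mirna_mrna":
            vals = [pearson(mprof[m], gprof[g])
                    for m in mirnas for g in genes
                    if m in mprof and g in gprof]
        else:
            vals = [pearson(gprof[g1], gprof[g2])
                    for g1, g2 in itertools.combinations(genes, 2)
                    if g1 in gprof and g2 in gprof]
        out.append(np.asarray(vals, dtype=float))
    return out


def sample_random_background(
    mtbs: Sequence[MTB],
    mirna_pool: Sequence[str],
    mrna_pool: Sequence[str],
    n_sets: int,
    seed: int,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    t: float,
    pair_kind: Literal["mirna_mrna", "mrna_mrna"] = "mirna_mrna",
) -> np.ndarray:
    """Fractions from random modules with sizes drawn from the MTB size list.

    Each synthetic module draws one (n_mrnas, n_mirnas) pair uniformly from
    the observed module sizes and samples members uniformly without
    replacement from the expressed pools; fully seeded and reproducible.
    """
    if n_sets == 0:
        return np.array([])
    direction = "below" if pair_kind == "mirna_mrna" else "above"
    values = _random_set_values(mtbs, mirna_pool, mrna_pool, n_sets, seed,
                                expr_mirna, expr_mrna, pair_kind)
    return np.array([fraction_beyond(v, t, direction) for v in values])


def _co_membership(mtbs: Sequence[MTB]) -> set[frozenset]:
    pairs: set[frozenset] = set()
    for b in mtbs:
        for i1, i2 in itertools.combinations(sorted(b.rows), 2):
            pairs.add(frozenset((i1, i2)))
    return pairs


def _outside_values(
    network: InteractionNetwork,
    mtbs: Sequence[MTB],
    mode: str,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
) -> list[np.ndarray]:
    """Per-module out-of-module correlation (or d) values."""
    adj = network.adjacency
    col_targets = [set(np.nonzero(adj[:, j])[0].tolist())
                   for j in range(network.n_mirnas)]
    gprof = _profiles(expr_mrna, network.mrna_ids)
    mprof = _profiles(expr_mirna, network.mirna_ids)
    gid = network.mrna_ids
    mid = network.mirna_ids
    out: list[np.ndarray] = []
    if mode == "mirna_targets":
        for b in mtbs:
            vals = [pearson(mprof[mid[j]], gprof[gid[i]])
                    for j in sorted(b.cols)
                    for i in sorted(col_targets[j] - b.rows)
                    if mid[j] in mprof and gid[i] in gprof]
            out.append(np.asarray(vals, dtype=float))
    elif mode == "shared_mirna_mrna_pairs":
        co = _co_membership(mtbs)
        for b in _eligible(mtbs, "mrna_mrna"):
            seen: set[frozenset] = set()
            vals = []
            for j in sorted(b.cols):
                for i1, i2 in itertools.combinations(sorted(col_targets[j]), 2):
                    key = frozenset((i1, i2))
                    if key in seen or key in co:
                        continue
                    seen.add(key)
                    if gid[i1] in gprof and gid[i2] in gprof:
                        vals.append(pearson(gprof[gid[i1]], gprof[gid[i2]]))
            out.append(np.asarray(vals, dtype=float))
    elif mode == "triples":
        for b in mtbs:
            vals = []
            for j in sorted(b.cols):
                outside = sorted(col_targets[j] - b.rows)
                for i1, i2 in itertools.permutations(outside, 2):
                    if gid[i1] in gprof and gid[i2] in gprof \
                            and mid[j] in mprof:
                        vals.append(d_statistic(mprof[mid[j]],
                                                gprof[gid[i1]],
                                                gprof[gid[i2]]))
            out.append(np.asarray(vals, dtype=float))
    else:
        raise ValueError(f"unknown outside-background mode {mode!r}")
    for b, vals in zip(mtbs, out):
        if vals.size == 0:
            logger.info("module %dx%d has no outside counterpart",
                        b.n_mrnas, b.n_mirnas)
    return out


def outside_background(
    network: InteractionNetwork,
    mtbs: Sequence[MTB],
    mode: Literal["mirna_targets", "shared_mirna_mrna_pairs", "triples"],
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    t: float,
) -> np.ndarray:
    """Per-module fractions from matched out-of-module counterparts.

    ``mirna_targets``: the module's miRNAs paired with their targets outside
    the module (fraction below t).  ``shared_mirna_mrna_pairs``: mRNA pairs
    targeted by a common module miRNA but never co-occurring in any module of
    the list (fraction above t).  ``triples``: buffering triples (R, T1, T2)
    with R in the module and T1, T2 targets of R outside it (fraction of d
    below t).  Modules with no counterpart yield NaN.
    """
    direction = "above" if mode == "shared_mirna_mrna_pairs" else "below"
    values = _outside_values(network, mtbs, mode, expr_mirna, expr_mrna)
    return np.array([fraction_beyond(v, t, direction) for v in values])


def wilcoxon_one_sided(
    sample_a,
    sample_b,
    alternative: Literal["a_greater", "a_less"] = "a_greater",
) -> float:
    """One-sided Wilcoxon rank-sum p-value, floored at 1e-16.

    NaNs are dropped first.  For combined sample sizes up to 12 without ties
    the exact permutation distribution of the rank sum is used; otherwise the
    normal approximation with midranks and tie-corrected variance.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample after NaN removal")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    alt = "greater" if alternative == "a_greater" else "less"
    res = scipy.stats.mannwhitneyu(a, b, alternative=alt, method=method)
    return float(min(1.0, max(P_FLOOR, res.pvalue)))


def evaluate_workflow(
    mtbs: Sequence[MTB],
    network: InteractionNetwork,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    grid: ThresholdGrid | None = None,
    background: Literal["random_sets", "outside_pairs"] = "random_sets",
    n_random: int = 1000,
    seed: int = 0,
    pair_kind: Literal["mirna_mrna", "mrna_mrna"] = "mirna_mrna",
    background_mtbs: Sequence[MTB] | None = None,
    mtb_type: str | None = None,
) -> list[EvalResult]:
    """Full correlation workflow: fractions, background, Wilcoxon per t.

    Pair correlations are computed once per module (and once per background
    unit) and re-thresholded for every t in the grid.  *background* selects
    random size-matched sets or the out-of-module construction matching
    *pair_kind*; an externally supplied module list (e.g. modules from
    another method) can be passed as *background_mtbs* instead, in which case
    the comparison is foreground modules vs external modules.
    """
    if grid is None:
        grid = (ThresholdGrid.anticorrelation() if pair_kind == "mirna_mrna"
                else ThresholdGrid.positive())
    eligible = _eligible(mtbs, pair_kind)
    if not eligible:
        raise ValueError("no eligible modules for this analysis")
    label = mtb_type or eligible[0].mtb_type
    direction = "below" if pair_kind == "mirna_mrna" else "above"
    fg_values = [_mtb_pair_values(b, network, expr_mirna, expr_mrna, pair_kind)
                 for b in eligible]
    if background_mtbs is not None:
        bg_values = [
            _mtb_pair_values(b, network, expr_mirna, expr_mrna, pair_kind)
            for b in _eligible(background_mtbs, pair_kind)]
        kind = "mrm_list"
    elif background == "random_sets":
        bg_values = _random_set_values(
            mtbs, network.mirna_ids, network.mrna_ids, n_random, seed,
            expr_mirna, expr_mrna, pair_kind)
        kind = "random_sets"
    elif background == "outside_pairs":
        mode = ("mirna_targets" if pair_kind == "mirna_mrna"
                else "shared_mirna_mrna_pairs")
        bg_values = _outside_values(network, mtbs, mode,
                                    expr_mirna, expr_mrna)
        kind = "outside_pairs"
    else:
        raise ValueError(f"unknown background {background!r}")
    results = []
    for t in grid.values:
        fg = np.array([fraction_beyond(v, t, direction) for v in fg_values])
        bg = np.array([fraction_beyond(v, t, direction) for v in bg_values])
        p = wilcoxon_one_sided(fg, bg, "a_greater")
        results.append(EvalResult(label, t, fg, bg, p, kind))
    return results


def _inside_triple_values(
    mtbs: Sequence[MTB],
    network: InteractionNetwork,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
) -> tuple[list[MTB], list[np.ndarray]]:
    """d values of within-module triples; modules without triples dropped.

    A triple requires the regulator to target both mRNAs by network edge,
    with all three inside the module.
    """
    adj = network.adjacency
    gprof = _profiles(expr_mrna, network.mrna_ids)
    mprof = _profiles(expr_mirna, network.mirna_ids)
    gid, mid = network.mrna_ids, network.mirna_ids
    kept, values = [], []
    for b in mtbs:
        vals = []
        for j in sorted(b.cols):
            targets = [i for i in sorted(b.rows) if adj[i, j]]
            for i1, i2 in itertools.permutations(targets, 2):
                if mid[j] in mprof and gid[i1] in gprof and gid[i2] in gprof:
                    vals.append(d_statistic(mprof[mid[j]], gprof[gid[i1]],
                                            gprof[gid[i2]]))
        if vals:
            kept.append(b)
            values.append(np.asarray(vals, dtype=float))
        else:
            logger.info("module %dx%d skipped: no eligible triples",
                        b.n_mrnas, b.n_mirnas)
    return kept, values


def buffering_workflow(
    mtbs: Sequence[MTB],
    network: InteractionNetwork,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    grid: ThresholdGrid | None = None,
    mtb_type: str | None = None,
) -> list[EvalResult]:
    """Buffering workflow: within-module d fractions vs outside triples.

    For every module the fraction of (R, T1, T2) triples with d below t is
    compared (one-sided Wilcoxon, foreground greater) against the matching
    fraction over triples with the same regulators but both targets outside
    the module.
    """
    if grid is None:
        grid = ThresholdGrid.anticorrelation()
    kept, fg_values = _inside_triple_values(mtbs, network,
                                            expr_mirna, expr_mrna)
    if not kept:
        raise ValueError("no modules with eligible buffering triples")
    label = mtb_type or kept[0].mtb_type
    bg_values = _outside_values(network, kept, "triples",
                                expr_mirna, expr_mrna)
    results = []
    for t in grid.values:
        fg = np.array([fraction_beyond(v, t, "below") for v in fg_values])
        bg = np.array([fraction_beyond(v, t, "below") for v in bg_values])
        p = wilcoxon_one_sided(fg, bg, "a_greater")
        results.append(EvalResult(label, t, fg, bg, p, "outside_triples"))
    return results


def per_mtb_mean_d(
    mtbs: Sequence[MTB],
    network: InteractionNetwork,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
) -> tuple[list[MTB], np.ndarray]:
    """Mean buffering d over within-module triples, per module.

    Modules without eligible triples are dropped.  The arithmetic mean is the
    per-module aggregate used for top/bottom ranking.
    """
    kept, values = _inside_triple_values(mtbs, network, expr_mirna, expr_mrna)
    means = np.array([float(np.nanmean(v)) if np.any(~np.isnan(v))
                      else float("nan") for v in values])
    keep = ~np.isnan(means)
    return [b for b, k in zip(kept, keep) if k], means[keep]


def rank_top_bottom(
    mtbs: Sequence[MTB],
    mean_d: Sequence[float],
    x: int,
) -> tuple[list[MTB], list[MTB]]:
    """The x modules with the most negative / most positive mean d.

    Ties at the boundary are broken by the modules' deterministic sort key.
    An x larger than the list is clipped with a warning.
    """
    mean_d = np.asarray(mean_d, dtype=float)
    if len(mtbs) != mean_d.size:
        raise ValueError("mtbs and mean_d lengths differ")
    if np.isnan(mean_d).any():
        raise ValueError("mean_d must be defined for every module")
    if x > len(mtbs):
        warnings.warn(f"x={x} exceeds the {len(mtbs)} ranked modules; clipped",
                      stacklevel=2)
        x = len(mtbs)
    order = sorted(range(len(mtbs)),
                   key=lambda i: (mean_d[i],) + mtbs[i].sort_key())
    top = [mtbs[i] for i in order[:x]]
    bottom = [mtbs[i] for i in order[::-1][:x]]
    return top, bottom


@dataclass
class GridComparison:
    """Outcome of the top-vs-bottom comparison over the parameter grid."""

    rows: list  # (network, x, t, p_top, p_bottom)
    n_settings: int
    n_top_wins: int  # settings where p_top <= p_bottom

    def to_records(self) -> list[dict]:
        return [dict(network=n, x=x, t=t, p_top=pt, p_bottom=pb)
                for n, x, t, pt, pb in self.rows]


def grid_comparison(
    datasets: Mapping[str, tuple],
    grid_spec: GridSpec,
    seed: int = 0,
) -> GridComparison:
    """Top-vs-bottom mRNA-correlation comparison over the (network, x, t) grid.

    *datasets* maps each network label of the grid to a tuple
    ``(mtbs, network, expr_mirna, expr_mrna)``.  For every cell, the modules
    are ranked by mean within-module d, the x most negative ("top") and most
    positive ("bottom") are selected, and the mRNA positive-correlation
    workflow (background: mRNA pairs sharing a targeting miRNA outside the
    modules) is run on each half at threshold t.  A cell counts as a top win
    when the top half's p-value is less than or equal to the bottom's.
    """
    labels = grid_spec.networks or tuple(datasets)
    rows = []
    n_top_wins = 0
    for label in labels:
        mtbs, network, expr_mirna, expr_mrna = datasets[label]
        ranked, mean_d = per_mtb_mean_d(mtbs, network, expr_mirna, expr_mrna)
        for x in grid_spec.x_values:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                top, bottom = rank_top_bottom(ranked, mean_d, x)
            halves = []
            for half in (top, bottom):
                res = evaluate_workflow(
                    half, network, expr_mirna, expr_mrna,
                    grid=ThresholdGrid(grid_spec.t_values),
                    background="outside_pairs", pair_kind="mrna_mrna",
                    seed=seed)
                halves.append({r.t: r.p_value for r in res})
            for t in grid_spec.t_values:
                p_top, p_bottom = halves[0][t], halves[1][t]
                if p_top <= p_bottom:
                    n_top_wins += 1
                rows.append((label, x, float(t), p_top, p_bottom))
    return GridComparison(rows, len(labels) * len(grid_spec.x_values)
                          * len(grid_spec.t_values), n_top_wins)
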