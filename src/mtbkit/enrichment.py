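"""Per-module functional enrichment: hypergeometric tail, EASE score,
best-term collection, and the three background comparisons.

For a module with n annotated genes out of a background universe of N, a
term annotating K universe genes and k module genes, the enrichment p-value
is the hypergeometric upper tail P(X >= k).  The EASE score is the same tail
computed after removing one gene from the overlap (k -> k-1), a deliberately
conservative variant that penalises single-gene overlaps.  Each module
contributes its most significant term; the distribution of per-module
-log10 p values is compared against random size-matched gene sets, the
module miRNAs' outside targets, or random sets additionally matched on mean
pairwise co-expression.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .core import MTB
from .evalstats import EvalResult, wilcoxon_one_sided
from .expression import pearson
from .netio import ExpressionMatrix, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "hypergeom_upper",
    "ease_score",
    "best_enrichment",
    "coexpression_matched_sets",
    "enrichment_workflow",
]


@dataclass(frozen=True)
class AnnotationMap:
    """Gene -> term annotations with their inverse and background universe."""

    gene_to_terms: dict
    term_to_genes: dict
    background_genes: frozenset

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationMap":
        g2t: dict[str, set] = {}
        t2g: dict[str, set] = {}
        for gene, term in pairs:
            g2t.setdefault(gene, set()).add(term)
            t2g.setdefault(term, set()).add(gene)
        return cls({g: frozenset(t) for g, t in g2t.items()},
                   {t: frozenset(g) for t, g in t2g.items()},
                   frozenset(g2t))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        """Two-column TSV ``gene_id<TAB>term_id``; extra columns ignored."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: annotation table needs two columns")
        return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for gene in sorted(self.gene_to_terms):
                for term in sorted(self.gene_to_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")

    def restricted_to(self, genes: Iterable[str]) -> "AnnotationMap":
        """Annotation restricted to a gene universe (e.g. expressed genes)."""
        keep = set(genes) & set(self.background_genes)
        pairs = [(g, t) for g in sorted(keep)
                 for t in sorted(self.gene_to_terms[g])]
        return AnnotationMap.from_pairs(pairs)


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    _validate_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(min(1.0, scipy.stats.hypergeom.sf(k - 1, N, K, n)))


def ease_score(k: int, K: int, n: int, N: int) -> float:
    """EASE score: the hypergeometric tail with one overlap gene removed.

    Equals ``hypergeom_upper(k - 1, K, n, N)``; overlaps of at most one gene
    score 1.0.  Always at least as large as the plain hypergeometric p.
    """
    _validate_counts(k, K, n, N)
    if k <= 1:
        return 1.0
    return hypergeom_upper(k - 1, K, n, N)


_SCORERS = {"hypergeom": hypergeom_upper, "ease": ease_score}


def best_enrichment(
    gene_set: Iterable[str],
    annotation: AnnotationMap,
    scorer: Literal["hypergeom", "ease"] = "hypergeom",
) -> tuple[str | None, float]:
    """Most significant term for a gene set: (term_id, p), ties by term id.

    Only genes in the annotation universe count towards the drawn-set size n;
    every term annotated to at least one member gene is evaluated.  A set
    with no annotated member yields (None, NaN).
    """
    score = _SCORERS[scorer]
    genes = set(gene_set) & set(annotation.background_genes)
    if not genes:
        logger.info("gene set has no annotated member")
        return None, float("nan")
    N = len(annotation.background_genes)
    n = len(genes)
    terms = sorted({t for g in genes for t in annotation.gene_to_terms[g]})
    best_term, best_p = None, np.inf
    for term in terms:
        members = annotation.term_to_genes[term]
        p = score(len(genes & members), len(members), n, N)
        if p < best_p:
            best_term, best_p = term, p
    return best_term, float(best_p)


def _mean_pairwise_correlation(genes: Sequence[str],
                               profiles: dict) -> float:
    vals = [pearson(profiles[a], profiles[b])
            for a, b in itertools.combinations(genes, 2)
            if a in profiles and b in profiles]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def coexpression_matched_sets(
    gene_set: Sequence[str],
    expr_mrna: ExpressionMatrix,
    n_sets: int,
    seed: int,
    tolerance: float = 0.1,
    pool: Sequence[str] | None = None,
    max_tries: int = 200,
) -> list[list[str]]:
    """Random gene sets matched in size and mean pairwise co-expression.

    Sets of the same size as *gene_set* are rejection-sampled from *pool*
    (default: all genes with expression) until their mean pairwise Pearson
    correlation lies within *tolerance* of the target set's.  Each set gets
    at most *max_tries* attempts; unmatched sets are skipped with a warning,
    so fewer than *n_sets* sets may be returned.  A tolerance of 1.0 or a NaN
    target reduces to plain size-matched sampling.
    """
    pool = sorted(pool if pool is not None else expr_mrna.entity_ids)
    size = len(set(gene_set))
    if size > len(pool):
        raise ValueError("gene pool smaller than the target set")
    profiles = {g: expr_mrna.values[i] for g, i in expr_mrna.index().items()}
    target = _mean_pairwise_correlation(sorted(set(gene_set)), profiles)
    vacuous = tolerance >= 1.0 or np.isnan(target)
    rng = np.random.default_rng(seed)
    out: list[list[str]] = []
    n_failed = 0
    for _ in range(n_sets):
        for _ in range(max_tries):
            cand = sorted(rng.choice(pool, size=size, replace=False))
            if vacuous or abs(
                    _mean_pairwise_correlation(cand, profiles) - target
                    ) <= tolerance:
                out.append(cand)
                break
        else:
            n_failed += 1
    if n_failed:
        warnings.warn(f"{n_failed} of {n_sets} co-expression-matched sets "
                      f"could not be sampled within {max_tries} tries",
                      stacklevel=2)
    return out


def enrichment_workflow(
    mtbs: Sequence[MTB],
    annotation: AnnotationMap,
    network: InteractionNetwork,
    expr_mrna: ExpressionMatrix | None = None,
    background: Literal["random_sets", "outside_genes",
                        "coexpressed_sets"] = "random_sets",
    scorer: Literal["hypergeom", "ease"] = "hypergeom",
    n_sets: int = 1000,
    seed: int = 0,
    coexpr_tolerance: float = 0.1,
    mtb_type: str | None = None,
) -> EvalResult:
    """Per-module best-enrichment scores compared against a background.

    Foreground: each module's most significant term p, as -log10 p.
    Backgrounds: size-matched random gene sets; the module miRNAs' targets
    outside the module; or random sets additionally matched on mean pairwise
    co-expression (requires *expr_mrna*).  The two distributions of -log10 p
    are compared with a one-sided Wilcoxon rank-sum test (foreground
    greater), so a small p-value means the modules' genes share annotation
    terms more strongly than the background.
    """
    if not mtbs:
        raise ValueError("no modules given")
    universe = annotation.restricted_to(network.mrna_ids)
    gid = network.mrna_ids

    def neglog_best(genes: Iterable[str]) -> float:
        _, p = best_enrichment(genes, universe, scorer)
        return float(-np.log10(p)) if not np.isnan(p) else float("nan")

    module_genes = [[gid[i] for i in sorted(b.rows)] for b in mtbs]
    fg = np.array([neglog_best(genes) for genes in module_genes])
    rng = np.random.default_rng(seed)
    pool = sorted(universe.background_genes)
    if background == "random_sets":
        sizes = [len(g) for g in module_genes]
        if max(sizes) > len(pool):
            raise ValueError("annotated gene pool smaller than largest module")
        bg = np.array([
            neglog_best(rng.choice(pool,
                                   size=sizes[rng.integers(len(sizes))],
                                   replace=False))
            for _ in range(n_sets)])
        kind = "random_sets"
    elif background == "outside_genes":
        adj = network.adjacency
        bg_list = []
        for b in mtbs:
            outside = set()
            for j in sorted(b.cols):
                outside |= set(np.nonzero(adj[:, j])[0].tolist()) - b.rows
            bg_list.append(neglog_best(gid[i] for i in sorted(outside))
                           if outside else float("nan"))
        bg = np.array(bg_list)
        kind = "outside_pairs"
    elif background == "coexpressed_sets":
        if expr_mrna is None:
            raise ValueError("coexpressed_sets background needs expr_mrna")
        bg_list = []
        per_module = int(np.ceil(n_sets / len(mtbs)))
        for i, genes in enumerate(module_genes):
            sets = coexpression_matched_sets(
                genes, expr_mrna, per_module,
                seed=int(rng.integers(2**31)), tolerance=coexpr_tolerance,
                pool=pool)
            bg_list.extend(neglog_best(s) for s in sets)
        bg = np.array(bg_list[:n_sets])
        kind = "random_sets"
    else:
        raise ValueError(f"unknown background {background!r}")
    p = wilcoxon_one_sided(fg, bg, "a_greater")
    label = mtb_type or mtbs[0].mtb_type
    return EvalResult(label, float("nan"), fg, bg, p, kind)
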