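"""Reading, integration and filtering of miRNA-target networks and expression tables.

A miRNA-target network is held as a binary biadjacency matrix whose rows are
mRNAs and whose columns are miRNAs.  Networks are assembled from per-method
prediction tables by taking the union of the top-k highest-scoring predictions
of each method (ties at the cutoff included), optionally merged with a set of
experimentally validated pairs.  Expression tables (entities x samples, e.g.
RPKM values) drive the "expressed entity" filter and the miRNA variant
grouping used by the correlation workflows.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionRecord",
    "InteractionNetwork",
    "ExpressionMatrix",
    "read_prediction_table",
    "select_top_k",
    "build_union_network",
    "filter_to_expressed",
    "average_replicates",
    "group_mirna_variants",
]


@dataclass(frozen=True)
class PredictionRecord:
    """One scored miRNA->mRNA prediction; scores are internally higher=better."""

    mirna_id: str
    mrna_id: str
    score: float
    source: str

    def __post_init__(self) -> None:
        if not self.mirna_id or not self.mrna_id:
            raise ValueError("prediction record requires non-empty ids")
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score for pair "
                             f"({self.mirna_id}, {self.mrna_id})")


@dataclass
class InteractionNetwork:
    """Binary biadjacency over labelled mRNA rows and miRNA columns."""

    mrna_ids: list[str]
    mirna_ids: list[str]
    adjacency: np.ndarray  # shape (n_mrnas, n_mirnas), values in {0, 1}

    def __post_init__(self) -> None:
        self.mrna_ids = list(self.mrna_ids)
        self.mirna_ids = list(self.mirna_ids)
        self.adjacency = np.asarray(self.adjacency, dtype=np.uint8)
        if len(set(self.mrna_ids)) != len(self.mrna_ids):
            raise ValueError("duplicate mRNA ids")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids")
        if self.adjacency.shape != (len(self.mrna_ids), len(self.mirna_ids)):
            raise ValueError("adjacency dimensions do not match id lists")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be binary")

    @property
    def n_mrnas(self) -> int:
        return len(self.mrna_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def mrna_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.mrna_ids)}

    def mirna_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.mirna_ids)}

    def edges(self) -> list[tuple[str, str]]:
        """All (mirna_id, mrna_id) pairs with an interaction."""
        rows, cols = np.nonzero(self.adjacency)
        return [(self.mirna_ids[j], self.mrna_ids[i]) for i, j in zip(rows, cols)]

    @classmethod
    def from_edges(
        cls,
        pairs: Iterable[tuple[str, str]],
        mrna_ids: Sequence[str] | None = None,
        mirna_ids: Sequence[str] | None = None,
    ) -> "InteractionNetwork":
        """Build a network from (mirna_id, mrna_id) pairs.

        Row and column orders are lexicographic unless explicit id lists are
        given (ids absent from the lists raise an error).
        """
        pairs = list(pairs)
        if mrna_ids is None:
            mrna_ids = sorted({g for _, g in pairs})
        if mirna_ids is None:
            mirna_ids = sorted({m for m, _ in pairs})
        net = cls(list(mrna_ids), list(mirna_ids),
                  np.zeros((len(mrna_ids), len(mirna_ids)), dtype=np.uint8))
        gi, mi = net.mrna_index(), net.mirna_index()
        for m, g in pairs:
            if g not in gi or m not in mi:
                raise ValueError(f"pair ({m}, {g}) outside provided id lists")
            net.adjacency[gi[g], mi[m]] = 1
        return net

    def to_json(self, path: str | Path) -> None:
        rows, cols = np.nonzero(self.adjacency)
        payload = {
            "mrna_ids": self.mrna_ids,
            "mirna_ids": self.mirna_ids,
            "edges": [[int(i), int(j)] for i, j in zip(rows, cols)],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "InteractionNetwork":
        payload = json.loads(Path(path).read_text())
        adj = np.zeros((len(payload["mrna_ids"]), len(payload["mirna_ids"])),
                       dtype=np.uint8)
        for i, j in payload["edges"]:
            adj[i, j] = 1
        return cls(payload["mrna_ids"], payload["mirna_ids"], adj)

    @classmethod
    def from_edge_tsv(cls, path: str | Path) -> "InteractionNetwork":
        """Read an edge-list TSV with header columns mirna_id, mrna_id."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        for col in ("mirna_id", "mrna_id"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        return cls.from_edges(zip(df["mirna_id"], df["mrna_id"]))


@dataclass
class ExpressionMatrix:
    """Entity x sample table of non-negative expression values (e.g. RPKM)."""

    entity_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.entity_ids = list(self.entity_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids")
        if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
            raise ValueError("value dimensions do not match id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entity_ids)}

    def profile(self, entity_id: str) -> np.ndarray:
        return self.values[self.index()[entity_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "entity_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls.from_frame(df)


def read_prediction_table(
    path: str | Path,
    source: str,
    score_column: str = "score",
    score_direction: str = "higher_better",
    gene_symbol_map: Mapping[str, str] | None = None,
) -> list[PredictionRecord]:
    """Parse a per-method prediction TSV into scored records.

    The file must be tab-separated with a header naming at least ``mirna_id``,
    ``mrna_id`` and *score_column*; lines starting with ``#`` are skipped.
    When *score_direction* is ``"lower_better"`` scores are negated so that
    internally a higher score always means a more confident prediction.
    *gene_symbol_map* optionally remaps mRNA identifiers to official symbols;
    records whose gene is not in the map are dropped (with a logged count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"prediction table not found: {path}")
    if score_direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown score_direction {score_direction!r}")
    records: list[PredictionRecord] = []
    header: list[str] | None = None
    n_unmapped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if header is None:
                header = fields
                for col in ("mirna_id", "mrna_id", score_column):
                    if col not in header:
                        raise ValueError(
                            f"{path}: missing required column {col!r}")
                continue
            row = dict(zip(header, fields))
            mirna = row.get("mirna_id", "")
            mrna = row.get("mrna_id", "")
            if not mirna or not mrna:
                raise ValueError(f"{path}: empty id on line {lineno}")
            try:
                score = float(row[score_column])
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"{path}: unparseable {score_column!r} on line {lineno}"
                ) from exc
            if gene_symbol_map is not None:
                if mrna not in gene_symbol_map:
                    n_unmapped += 1
                    continue
                mrna = gene_symbol_map[mrna]
            if score_direction == "lower_better":
                score = -score
            records.append(PredictionRecord(mirna, mrna, score, source))
    if header is None or not records and n_unmapped == 0:
        raise ValueError(f"{path}: empty prediction table "
                         f"(score column {score_column!r})")
    if n_unmapped:
        logger.info("%s: dropped %d records with unrecognized gene names",
                    path, n_unmapped)
    return records


def select_top_k(records: Sequence[PredictionRecord],
                 k: int) -> set[tuple[str, str]]:
    """Pairs whose score reaches the k-th largest; cutoff ties all included.

    The result may therefore contain slightly more than *k* pairs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not records:
        warnings.warn("select_top_k called with no records", stacklevel=2)
        return set()
    scores = sorted((r.score for r in records), reverse=True)
    cutoff = scores[min(k, len(scores)) - 1]
    return {(r.mirna_id, r.mrna_id) for r in records if r.score >= cutoff}


def build_union_network(
    pair_sets: Sequence[set[tuple[str, str]]],
    validated_pairs: set[tuple[str, str]] | None = None,
) -> InteractionNetwork:
    """Union of per-method pair sets, optionally merged with validated pairs."""
    if not pair_sets or all(not s for s in pair_sets):
        raise ValueError("at least one non-empty pair set required")
    union: set[tuple[str, str]] = set()
    for s in pair_sets:
        union |= set(s)
    if validated_pairs:
        union |= set(validated_pairs)
    return InteractionNetwork.from_edges(sorted(union))


def _expressed_ids(expr: ExpressionMatrix, min_nonzero: int) -> set[str]:
    counts = (expr.values > 0).sum(axis=1)
    return {e for e, c in zip(expr.entity_ids, counts) if c >= min_nonzero}


def filter_to_expressed(
    network: InteractionNetwork,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    min_nonzero: int = 8,
    n_samples: int = 10,
) -> InteractionNetwork:
    """Restrict a network to entities expressed in enough samples.

    An entity is kept when its expression profile has at least *min_nonzero*
    non-zero values across the *n_samples* samples; entities absent from the
    expression tables are treated as not expressed and removed together with
    their edges.
    """
    if min_nonzero > n_samples:
        raise ValueError("min_nonzero cannot exceed n_samples")
    for name, expr in (("miRNA", expr_mirna), ("mRNA", expr_mrna)):
        if expr.n_samples != n_samples:
            raise ValueError(
                f"{name} expression table has {expr.n_samples} samples, "
                f"expected {n_samples}")
    keep_mirnas = _expressed_ids(expr_mirna, min_nonzero)
    keep_mrnas = _expressed_ids(expr_mrna, min_nonzero)
    rows = [i for i, g in enumerate(network.mrna_ids) if g in keep_mrnas]
    cols = [j for j, m in enumerate(network.mirna_ids) if m in keep_mirnas]
    return InteractionNetwork(
        [network.mrna_ids[i] for i in rows],
        [network.mirna_ids[j] for j in cols],
        network.adjacency[np.ix_(rows, cols)] if rows and cols
        else np.zeros((len(rows), len(cols)), dtype=np.uint8),
    )


def average_replicates(
    tables: Sequence[ExpressionMatrix],
    replicate_groups: Mapping[str, str],
) -> ExpressionMatrix:
    """Average replicate sample columns of the same experiment.

    All tables must cover the same entities; columns across tables are pooled
    and grouped by ``replicate_groups[sample_id]``.  Output columns are the
    experiment names, ordered by first appearance, and hold the arithmetic
    mean over the group's replicates.
    """
    if not tables:
        raise ValueError("no expression tables given")
    base = tables[0]
    frames = [base.to_frame()]
    for t in tables[1:]:
        if set(t.entity_ids) != set(base.entity_ids):
            raise ValueError("expression tables cover different entities")
        frames.append(t.to_frame().reindex(base.entity_ids))
    pooled = pd.concat(frames, axis=1)
    experiments: list[str] = []
    members: dict[str, list[str]] = {}
    for sample in pooled.columns:
        if sample not in replicate_groups:
            raise ValueError(f"sample {sample!r} missing from replicate_groups")
        exp = replicate_groups[sample]
        if exp not in members:
            experiments.append(exp)
            members[exp] = []
        members[exp].append(sample)
    for exp in set(replicate_groups.values()):
        if exp not in members:
            raise ValueError(f"experiment {exp!r} has zero replicate columns")
    out = np.column_stack(
        [pooled[members[exp]].to_numpy(dtype=float).mean(axis=1)
         for exp in experiments])
    return ExpressionMatrix(base.entity_ids, experiments, out)


# miRNA ids look like <prefix>-<number>[letter][-5p|-3p]; the numeric core with
# its prefix identifies the variant group (e.g. hsa-mir-121a, hsa-mir-121b ->
# hsa-mir-121; miR-17-5p, miR-17-3p -> miR-17).
_VARIANT_RE = re.compile(r"^(?P<core>.*?\d+)(?P<letter>[a-z])?(?P<arm>-[35]p)?$",
                         re.IGNORECASE)


def mirna_variant_core(mirna_id: str) -> str | None:
    """Numeric-core group name of a miRNA id, or None if unparseable."""
    m = _VARIANT_RE.match(mirna_id.strip())
    if m is None or not any(ch.isdigit() for ch in mirna_id):
        return None
    return m.group("core")


def group_mirna_variants(
    network: InteractionNetwork,
    expr_mirna: ExpressionMatrix,
) -> tuple[InteractionNetwork, ExpressionMatrix]:
    """Merge miRNA name variants sharing a numeric core.

    Variants such as ``hsa-mir-121a``/``hsa-mir-121b`` or ``miR-17-5p``/
    ``miR-17-3p`` are merged into a single column named by their common core.
    The merged column targets the union of the members' targets and its
    expression profile is the per-sample mean over members with expression
    data.  Ids without a parseable numeric core are left ungrouped (logged);
    singleton groups keep their original id.
    """
    groups: dict[str, list[str]] = {}
    for mid in network.mirna_ids:
        core = mirna_variant_core(mid)
        if core is None:
            logger.info("unparseable miRNA id left ungrouped: %s", mid)
            core = mid
        groups.setdefault(core, []).append(mid)
    new_ids = []
    for core, members in sorted(groups.items()):
        new_ids.append(core if len(members) > 1 else members[0])
    mi = network.mirna_index()
    adj = np.zeros((network.n_mrnas, len(new_ids)), dtype=np.uint8)
    for j, (core, members) in enumerate(sorted(groups.items())):
        cols = [mi[m] for m in members]
        adj[:, j] = network.adjacency[:, cols].max(axis=1)
    expr_index = expr_mirna.index()
    expr_ids, expr_rows = [], []
    for new_id, (core, members) in zip(new_ids, sorted(groups.items())):
        present = [expr_index[m] for m in members if m in expr_index]
        if present:
            expr_ids.append(new_id)
            expr_rows.append(expr_mirna.values[present].mean(axis=0))
    grouped_net = InteractionNetwork(network.mrna_ids, new_ids, adj)
    grouped_expr = ExpressionMatrix(
        expr_ids, expr_mirna.sample_ids,
        np.array(expr_rows) if expr_rows
        else np.zeros((0, expr_mirna.n_samples)))
    return grouped_net, grouped_expr
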