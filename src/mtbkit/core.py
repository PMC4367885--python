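"""Identification of microRNA-target biclusters (MTBs) of all eight types.

An MTB is a pair (r, c) of mRNA row indices and miRNA column indices of a
binary miRNA-target biadjacency matrix.  The eight types form a lattice along
two axes: whether the defining submatrix must be all 1's (restrictive, R) or
may contain 0's (loose, L), and whether extra 1's are permitted in the other
columns of the defining rows, the other rows of the defining columns, both,
or neither:

========  ==================  ==========================================
type      submatrix           out-of-module interactions allowed for
========  ==================  ==========================================
R         all 1's             neither side
Rmi       all 1's             mRNAs only (extra 1's on the rows)
Rm        all 1's             miRNAs only (extra 1's on the columns)
Rgen      all 1's             both sides (maximal bicliques)
L         0's allowed         neither side (connected components)
Lmi       0's allowed         mRNAs only
Lm        0's allowed         miRNAs only
Lgen      0's allowed         both sides
========  ==================  ==========================================

R, Rmi, Rm and L admit complete linear-time enumeration via row/column
signature hashing and breadth-first search.  Rgen uses level-wise (Apriori
style) closed-set enumeration of maximal bicliques.  The loose dense types
(Lmi, Lm, Lgen) are mined greedily: exact seeds are grown one column/row at
a time as long as the interaction density of the submatrix stays above a
threshold, returning high-density rather than maximal modules.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .netio import InteractionNetwork

__all__ = [
    "MTB",
    "MinerParams",
    "MTB_TYPES",
    "submatrix_density",
    "find_exact_R",
    "find_maximal_row_or_col_restricted",
    "find_maximal_Rgen",
    "find_components_L",
    "find_dense_one_side",
    "find_dense_Lgen",
    "dedup_similar",
    "summarize",
    "find_mtbs",
]

MTB_TYPES = ("R", "Rmi", "Rm", "Rgen", "L", "Lmi", "Lm", "Lgen")


@dataclass(frozen=True)
class MTB:
    """A (row-set, column-set) bicluster with its type tag and density."""

    rows: frozenset
    cols: frozenset
    mtb_type: str
    density: float

    def __post_init__(self) -> None:
        if not self.rows or not self.cols:
            raise ValueError("MTB requires non-empty row and column sets")
        if self.mtb_type not in MTB_TYPES:
            raise ValueError(f"unknown MTB type {self.mtb_type!r}")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError("density must lie in [0, 1]")

    @property
    def n_mrnas(self) -> int:
        return len(self.rows)

    @property
    def n_mirnas(self) -> int:
        return len(self.cols)

    def sort_key(self) -> tuple:
        """Deterministic ordering: bigger, denser, lexicographically first."""
        return (-(self.n_mrnas + self.n_mirnas), -self.density,
                tuple(sorted(self.rows)), tuple(sorted(self.cols)))

    def member_key(self, n_rows: int) -> frozenset:
        """Combined member set with rows and columns kept distinct."""
        return frozenset(self.rows) | frozenset(n_rows + j for j in self.cols)

    def to_dict(self, network: InteractionNetwork) -> dict:
        return {
            "type": self.mtb_type,
            "mrnas": [network.mrna_ids[i] for i in sorted(self.rows)],
            "mirnas": [network.mirna_ids[j] for j in sorted(self.cols)],
            "density": self.density,
        }


@dataclass(frozen=True)
class MinerParams:
    """Tuning knobs shared by all finders.

    density_threshold
        Minimum interaction density a greedy addition must preserve (the
        growth threshold of the dense loose types); default 0.3.
    min_mrnas, min_mirnas
        Minimum module side sizes in the reported output; default 2 and 2.
    similarity_threshold
        Jaccard similarity on combined member sets above which near-duplicate
        seeds are removed before greedy growth; default 0.9.
    max_candidates
        Cap on Apriori candidate column sets; exceeding it raises, advising a
        sparser network.
    """

    density_threshold: float = 0.3
    min_mrnas: int = 2
    min_mirnas: int = 2
    similarity_threshold: float = 0.9
    max_candidates: int = 10**6

    def __post_init__(self) -> None:
        if not (0.0 < self.density_threshold <= 1.0):
            raise ValueError("density_threshold must be in (0, 1]")
        if not (0.0 < self.similarity_threshold <= 1.0):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.min_mrnas < 1 or self.min_mirnas < 1:
            raise ValueError("minimum sizes must be >= 1")


def submatrix_density(network: InteractionNetwork,
                      rows: Iterable[int], cols: Iterable[int]) -> float:
    """Number of 1's divided by the number of cells of the submatrix."""
    rows, cols = sorted(set(rows)), sorted(set(cols))
    if not rows or not cols:
        raise ValueError("row and column sets must be non-empty")
    if rows[0] < 0 or rows[-1] >= network.n_mrnas \
            or cols[0] < 0 or cols[-1] >= network.n_mirnas:
        raise IndexError("submatrix index out of range")
    sub = network.adjacency[np.ix_(rows, cols)]
    return float(sub.sum()) / sub.size


def _row_signatures(adj: np.ndarray) -> list[frozenset]:
    return [frozenset(np.nonzero(adj[i])[0].tolist())
            for i in range(adj.shape[0])]


def _col_signatures(adj: np.ndarray) -> list[frozenset]:
    return [frozenset(np.nonzero(adj[:, j])[0].tolist())
            for j in range(adj.shape[1])]


def _size_filter(mtbs: Iterable[MTB], params: MinerParams) -> list[MTB]:
    out = [b for b in mtbs
           if b.n_mrnas >= params.min_mrnas and b.n_mirnas >= params.min_mirnas]
    return sorted(out, key=MTB.sort_key)


def find_exact_R(network: InteractionNetwork,
                 params: MinerParams = MinerParams()) -> list[MTB]:
    """All type R MTBs: all-1 submatrices with no extra 1's on either side.

    Rows are hashed by their column signature and grouped; a row group r with
    signature c is an MTB exactly when every column j in c belongs to a column
    group with signature r.  Runs in time linear in the number of 1's.
    """
    adj = network.adjacency
    row_sig = _row_signatures(adj)
    col_sig = _col_signatures(adj)
    row_groups: dict[frozenset, set[int]] = {}
    for i, sig in enumerate(row_sig):
        if sig:
            row_groups.setdefault(sig, set()).add(i)
    out = []
    for c, r in row_groups.items():
        r = frozenset(r)
        if all(col_sig[j] == r for j in c):
            out.append(MTB(r, frozenset(c), "R", 1.0))
    return _size_filter(out, params)


def find_maximal_row_or_col_restricted(
    network: InteractionNetwork,
    restrict: Literal["mirnas", "mrnas"],
    params: MinerParams = MinerParams(),
) -> list[MTB]:
    """Maximal type Rmi or Rm MTBs by signature grouping.

    ``restrict="mrnas"`` gives type Rmi (the mRNAs may be targeted by
    out-of-module miRNAs, the miRNAs may not have other targets): columns are
    grouped by identical row signature, and each group together with its
    signature rows is one maximal MTB.  ``restrict="mirnas"`` gives type Rm,
    the transpose.
    """
    mtbs = _maximal_one_side_restricted(network, restrict)
    return _size_filter(mtbs, params)


def _maximal_one_side_restricted(network: InteractionNetwork,
                                 restrict: str) -> list[MTB]:
    adj = network.adjacency
    if restrict == "mrnas":  # type Rmi: group columns by signature
        sigs = _col_signatures(adj)
        groups: dict[frozenset, set[int]] = {}
        for j, sig in enumerate(sigs):
            if sig:
                groups.setdefault(sig, set()).add(j)
        return [MTB(frozenset(r), frozenset(c), "Rmi", 1.0)
                for r, c in groups.items()]
    if restrict == "mirnas":  # type Rm: group rows by signature
        sigs = _row_signatures(adj)
        groups = {}
        for i, sig in enumerate(sigs):
            if sig:
                groups.setdefault(sig, set()).add(i)
        return [MTB(frozenset(r), frozenset(c), "Rm", 1.0)
                for c, r in groups.items()]
    raise ValueError(f"restrict must be 'mirnas' or 'mrnas', got {restrict!r}")


def find_maximal_Rgen(network: InteractionNetwork,
                      params: MinerParams = MinerParams()) -> list[MTB]:
    """All maximal bicliques (type Rgen) via level-wise closed-set search.

    Column sets are grown Apriori-style: k-column candidates are merged from
    (k-1)-column frequent sets sharing their first k-2 columns, and a
    candidate's support is the set of rows with 1's in all its columns.
    Candidates whose support falls below ``min_mrnas`` are pruned.  A set c
    with support r is reported when the pair is closed: c is exactly the set
    of columns with 1's in every row of r.
    """
    adj = network.adjacency
    n_rows, n_cols = adj.shape
    col_rows = [frozenset(np.nonzero(adj[:, j])[0].tolist())
                for j in range(n_cols)]
    min_sup = max(params.min_mrnas, 1)
    n_candidates = 0

    def closure_cols(rows: frozenset) -> frozenset:
        sub = adj[sorted(rows)]
        return frozenset(np.nonzero(sub.all(axis=0))[0].tolist())

    out: list[MTB] = []
    seen_closed: set[frozenset] = set()
    # level 1
    frequent: list[tuple[tuple, frozenset]] = []
    for j in range(n_cols):
        if len(col_rows[j]) >= min_sup:
            frequent.append(((j,), col_rows[j]))
    while frequent:
        for cols, rows in frequent:
            if closure_cols(rows) == frozenset(cols):
                key = frozenset(cols)
                if key not in seen_closed:
                    seen_closed.add(key)
                    out.append(MTB(rows, key, "Rgen",  1.0))
        nxt: list[tuple[tuple, frozenset]] = []
        for a in range(len(frequent)):
            cols_a, rows_a = frequent[a]
            for b in range(a + 1, len(frequent)):
                cols_b, rows_b = frequent[b]
                if cols_a[:-1] != cols_b[:-1]:
                    break  # sorted prefix order: no further merges for a
                n_candidates += 1
                if n_candidates > params.max_candidates:
                    raise RuntimeError(
                        "maximal-biclique candidate cap exceeded; the network "
                        "is too dense for exhaustive enumeration — consider a "
                        "sparser network or larger min_mrnas")
                rows_ab = rows_a & rows_b
                if len(rows_ab) >= min_sup:
                    nxt.append((cols_a + (cols_b[-1],), rows_ab))
        frequent = nxt
    return _size_filter(out, params)


def find_components_L(network: InteractionNetwork,
                      params: MinerParams = MinerParams()) -> list[MTB]:
    """Type L MTBs: connected components of the bipartite graph.

    Nodes of degree zero are ignored; each component is one MTB.  Linear-time
    breadth-first search.
    """
    adj = network.adjacency
    row_sig = _row_signatures(adj)
    col_sig = _col_signatures(adj)
    seen_rows: set[int] = set()
    seen_cols: set[int] = set()
    out = []
    for start in range(adj.shape[0]):
        if start in seen_rows or not row_sig[start]:
            continue
        comp_rows, comp_cols = set(), set()
        queue: deque = deque([("r", start)])
        seen_rows.add(start)
        while queue:
            kind, idx = queue.popleft()
            if kind == "r":
                comp_rows.add(idx)
                for j in row_sig[idx]:
                    if j not in seen_cols:
                        seen_cols.add(j)
                        queue.append(("c", j))
            else:
                comp_cols.add(idx)
                for i in col_sig[idx]:
                    if i not in seen_rows:
                        seen_rows.add(i)
                        queue.append(("r", i))
        rows, cols = frozenset(comp_rows), frozenset(comp_cols)
        out.append(MTB(rows, cols, "L",
                       submatrix_density(network, rows, cols)))
    return _size_filter(out, params)


def dedup_similar(mtbs: Sequence[MTB], similarity_threshold: float,
                  n_rows: int | None = None) -> list[MTB]:
    """Drop MTBs too similar to an already-retained one.

    MTBs are processed in descending (size, density, lexicographic-members)
    order; an MTB is dropped when the Jaccard similarity of its combined
    member set (rows and columns pooled, kept distinct) with any retained
    MTB exceeds the threshold.
    """
    if not (0.0 < similarity_threshold <= 1.0):
        raise ValueError("similarity threshold must be in (0, 1]")
    if n_rows is None:
        n_rows = 1 + max((max(b.rows) for b in mtbs), default=0)
    kept: list[MTB] = []
    kept_members: list[frozenset] = []
    for b in sorted(mtbs, key=MTB.sort_key):
        mem = b.member_key(n_rows)
        if any(len(mem & other) / len(mem | other) > similarity_threshold
               for other in kept_members):
            continue
        kept.append(b)
        kept_members.append(mem)
    return kept


def _grow_dense(
    network: InteractionNetwork,
    seeds: Sequence[MTB],
    params: MinerParams,
    mode: Literal["cols", "rows", "both"],
    out_type: str,
) -> list[MTB]:
    """Shared greedy growth engine for the dense loose types.

    Seeds (exact modules of density 1) are deduplicated, then grown one
    addition at a time.  In ``cols`` mode (type Lmi) only columns are added
    and every added column brings along all rows with a 1 in it; ``rows``
    mode (type Lm) is the transpose; ``both`` mode (type Lgen) adds single
    rows or columns without forced closure.  An addition is admissible when
    the enlarged submatrix keeps density >= the threshold and the new member
    has at least one interaction with the current members, so the module's
    induced subgraph stays connected.  Among admissible additions the one
    with the highest resulting density is taken (ties broken by kind then
    lowest index); growth stops when none qualifies.

    Two exclusion rules keep modules from dissolving into one another.
    First, members of an already grown module are not available to later
    ones: a seed is skipped outright when a previously grown module claimed
    any of its members, and claimed members are never candidates.  Second,
    growth may not invade foreign territory: a row or column belonging to a
    seed that shares no member with the module being grown is not a
    candidate (seeds overlapping the current module describe the same
    underlying module and do not protect their members).
    """
    adj = network.adjacency
    theta = params.density_threshold
    row_sig = _row_signatures(adj)
    col_sig = _col_signatures(adj)
    seeds = dedup_similar(seeds, params.similarity_threshold,
                          n_rows=network.n_mrnas)
    order = sorted(
        seeds,
        key=lambda b: (-b.density, -(b.n_mrnas * b.n_mirnas),
                       tuple(sorted(b.rows)), tuple(sorted(b.cols))))
    claimed_rows: set[int] = set()
    claimed_cols: set[int] = set()
    out: list[MTB] = []
    for seed in order:
        if seed.rows & claimed_rows or seed.cols & claimed_cols:
            continue
        rows, cols = set(seed.rows), set(seed.cols)
        ones = int(adj[np.ix_(sorted(rows), sorted(cols))].sum())
        while True:
            foreign_rows: set[int] = set()
            foreign_cols: set[int] = set()
            for s in order:
                if not (s.rows & rows or s.cols & cols):
                    foreign_rows |= s.rows
                    foreign_cols |= s.cols
            best = None  # (density, kind, index, new_rows, new_cols, ones)
            if mode in ("cols", "both"):
                for j in range(network.n_mirnas):
                    if j in cols or j in claimed_cols or j in foreign_cols:
                        continue
                    touch = len(col_sig[j] & rows)
                    if touch == 0:
                        continue  # would disconnect the module
                    if mode == "cols":
                        new_rows = rows | col_sig[j]
                        extra_rows = col_sig[j] - rows
                        if extra_rows & (claimed_rows | foreign_rows):
                            continue
                        new_ones = int(
                            adj[np.ix_(sorted(new_rows),
                                       sorted(cols | {j}))].sum())
                    else:
                        new_rows = rows
                        new_ones = ones + touch
                    dens = new_ones / (len(new_rows) * (len(cols) + 1))
                    if dens >= theta:
                        cand = (dens, 1, j, new_rows, cols | {j}, new_ones)
                        if best is None or (cand[0], -cand[1], -cand[2]) > \
                                (best[0], -best[1], -best[2]):
                            best = cand
            if mode in ("rows", "both"):
                for i in range(network.n_mrnas):
                    if i in rows or i in claimed_rows or i in foreign_rows:
                        continue
                    touch = len(row_sig[i] & cols)
                    if touch == 0:
                        continue
                    if mode == "rows":
                        new_cols = cols | row_sig[i]
                        extra_cols = row_sig[i] - cols
                        if extra_cols & (claimed_cols | foreign_cols):
                            continue
                        new_ones = int(
                            adj[np.ix_(sorted(rows | {i}),
                                       sorted(new_cols))].sum())
                    else:
                        new_cols = cols
                        new_ones = ones + touch
                    dens = new_ones / ((len(rows) + 1) * len(new_cols))
                    if dens >= theta:
                        cand = (dens, 0, i, rows | {i}, new_cols, new_ones)
                        if best is None or (cand[0], -cand[1], -cand[2]) > \
                                (best[0], -best[1], -best[2]):
                            best = cand
            if best is None:
                break
            _, _, _, rows, cols, ones = best
            rows, cols = set(rows), set(cols)
        dens = ones / (len(rows) * len(cols))
        out.append(MTB(frozenset(rows), frozenset(cols), out_type, dens))
        claimed_rows |= rows
        claimed_cols |= cols
    return _size_filter(out, params)


def find_dense_one_side(
    network: InteractionNetwork,
    restrict: Literal["mirnas", "mrnas"],
    params: MinerParams = MinerParams(),
) -> list[MTB]:
    """High-density type Lmi (``restrict="mrnas"``) or Lm MTBs.

    Seeds are the maximal one-side-restricted exact MTBs (type Rmi for Lmi,
    type Rm for Lm), used even when below the minimum output sizes; the size
    filter applies to the grown output only.  Growth adds whole columns
    (rows for Lm) together with all rows (columns) supporting them.
    """
    if restrict == "mrnas":
        seeds = [replace(b, mtb_type="Lmi")
                 for b in _maximal_one_side_restricted(network, "mrnas")]
        return _grow_dense(network, seeds, params, "cols", "Lmi")
    if restrict == "mirnas":
        seeds = [replace(b, mtb_type="Lm")
                 for b in _maximal_one_side_restricted(network, "mirnas")]
        return _grow_dense(network, seeds, params, "rows", "Lm")
    raise ValueError(f"restrict must be 'mirnas' or 'mrnas', got {restrict!r}")


def find_dense_Lgen(network: InteractionNetwork,
                    params: MinerParams = MinerParams()) -> list[MTB]:
    """High-density type Lgen MTBs grown from maximal bicliques.

    Seeds are the maximal bicliques meeting the minimum sizes; growth adds
    single rows or columns without forced closure while the density stays
    above the threshold and the module remains connected.
    """
    seeds = [replace(b, mtb_type="Lgen") for b in
             find_maximal_Rgen(network, params)]
    return _grow_dense(network, seeds, params, "both", "Lgen")


def summarize(mtbs: Sequence[MTB]) -> dict:
    """Count and mean side sizes of an MTB list (means are None when empty)."""
    if not mtbs:
        return {"count": 0, "mean_mrnas": None, "mean_mirnas": None}
    return {
        "count": len(mtbs),
        "mean_mrnas": float(np.mean([b.n_mrnas for b in mtbs])),
        "mean_mirnas": float(np.mean([b.n_mirnas for b in mtbs])),
    }


def save_mtbs(mtbs: Sequence[MTB], network: InteractionNetwork,
              path) -> None:
    """Write modules as JSON: a list of {type, mrnas, mirnas, density}."""
    import json
    from pathlib import Path
    Path(path).write_text(
        json.dumps([b.to_dict(network) for b in mtbs], indent=1))


def load_mtbs(path, network: InteractionNetwork) -> list[MTB]:
    """Read modules written by :func:`save_mtbs`, or any externally supplied
    module list in the same JSON shape, resolving ids against *network*."""
    import json
    from pathlib import Path
    gi, mi = network.mrna_index(), network.mirna_index()
    out = []
    for rec in json.loads(Path(path).read_text()):
        rows = frozenset(gi[g] for g in rec["mrnas"])
        cols = frozenset(mi[m] for m in rec["mirnas"])
        density = rec.get("density")
        if density is None:
            density = submatrix_density(network, rows, cols)
        out.append(MTB(rows, cols, rec.get("type", "Lgen"), float(density)))
    return out


def find_mtbs(network: InteractionNetwork, mtb_type: str,
              params: MinerParams = MinerParams()) -> list[MTB]:
    """Dispatch to the finder for *mtb_type* (one of the eight type tags)."""
    if mtb_type == "R":
        return find_exact_R(network, params)
    if mtb_type == "Rmi":
        return find_maximal_row_or_col_restricted(network, "mrnas", params)
    if mtb_type == "Rm":
        return find_maximal_row_or_col_restricted(network, "mirnas", params)
    if mtb_type == "Rgen":
        return find_maximal_Rgen(network, params)
    if mtb_type == "L":
        return find_components_L(network, params)
    if mtb_type == "Lmi":
        return find_dense_one_side(network, "mrnas", params)
    if mtb_type == "Lm":
        return find_dense_one_side(network, "mirnas", params)
    if mtb_type == "Lgen":
        return find_dense_Lgen(network, params)
    raise ValueError(f"unknown MTB type {mtb_type!r}")
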