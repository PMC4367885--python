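"""Brute-force enumeration oracles for the module-type predicates.

These deliberately use naive exhaustive search over row/column subsets (and
networkx for connected components) so they stay independent of the package's
signature-hashing and Apriori implementations.  Intended for small matrices
(up to ~12 columns/rows).
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

Module = tuple[frozenset, frozenset]  # (row indices, column indices)


def _row_sets(adj: np.ndarray) -> list[frozenset]:
    return [frozenset(np.nonzero(adj[i])[0].tolist())
            for i in range(adj.shape[0])]


def _col_sets(adj: np.ndarray) -> list[frozenset]:
    return [frozenset(np.nonzero(adj[:, j])[0].tolist())
            for j in range(adj.shape[1])]


def _subsets(n: int):
    for size in range(1, n + 1):
        yield from (frozenset(c)
                    for c in itertools.combinations(range(n), size))


def enumerate_R(adj: np.ndarray) -> set[Module]:
    """All-ones submatrices with no extra ones on their rows or columns."""
    row_sig, col_sig = _row_sets(adj), _col_sets(adj)
    out = set()
    for cols in _subsets(adj.shape[1]):
        rows = frozenset(i for i, s in enumerate(row_sig) if s == cols)
        if rows and all(col_sig[j] == rows for j in cols):
            out.add((rows, frozenset(cols)))
    return out


def enumerate_maximal_Rmi(adj: np.ndarray) -> set[Module]:
    """Maximal all-ones submatrices whose columns have no extra ones."""
    col_sig = _col_sets(adj)
    out = set()
    for cols in _subsets(adj.shape[1]):
        sigs = {col_sig[j] for j in cols}
        if len(sigs) != 1:
            continue
        rows = next(iter(sigs))
        if not rows:
            continue
        if any(col_sig[j] == rows for j in range(adj.shape[1])
               if j not in cols):
            continue  # not maximal: another column shares the signature
        out.add((rows, frozenset(cols)))
    return out


def enumerate_maximal_Rm(adj: np.ndarray) -> set[Module]:
    """Transpose of the Rmi predicate."""
    return {(cols, rows)
            for rows, cols in enumerate_maximal_Rmi(adj.T)}


def enumerate_maximal_bicliques(adj: np.ndarray) -> set[Module]:
    """Closed (row-set, column-set) pairs: maximal bicliques."""
    out = set()
    for cols in _subsets(adj.shape[1]):
        sub = adj[:, sorted(cols)]
        rows = frozenset(np.nonzero(sub.all(axis=1))[0].tolist())
        if not rows:
            continue
        closure = frozenset(
            np.nonzero(adj[sorted(rows)].all(axis=0))[0].tolist())
        if closure == cols:
            out.add((rows, frozenset(cols)))
    return out


def enumerate_components(adj: np.ndarray) -> set[Module]:
    """Connected components of the bipartite graph (degree-0 nodes ignored)."""
    g = nx.Graph()
    n_rows = adj.shape[0]
    for i, j in zip(*np.nonzero(adj)):
        g.add_edge(("r", int(i)), ("c", int(j)))
    out = set()
    for comp in nx.connected_components(g):
        rows = frozenset(i for kind, i in comp if kind == "r")
        cols = frozenset(j for kind, j in comp if kind == "c")
        out.add((rows, cols))
    return out


def size_filtered(modules: set[Module], min_rows: int = 2,
                  min_cols: int = 2) -> set[Module]:
    return {(r, c) for r, c in modules
            if len(r) >= min_rows and len(c) >= min_cols}


def random_binary_matrix(rng: np.random.Generator, n_rows: int, n_cols: int,
                         density: float) -> np.ndarray:
    return (rng.random((n_rows, n_cols)) < density).astype(np.uint8)


def oracle_matrix_stream(seed: int, n_matrices: int = 200):
    """Seeded stream of random test matrices (sizes 6-10, three densities)."""
    rng = np.random.default_rng(seed)
    for _ in range(n_matrices):
        n_rows = int(rng.integers(6, 11))
        n_cols = int(rng.integers(6, 11))
        density = float(rng.choice([0.2, 0.4, 0.6]))
        yield random_binary_matrix(rng, n_rows, n_cols, density)
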