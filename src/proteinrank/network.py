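"""Protein–protein interaction networks: loading, validation, indexing.

A :class:`PPINetwork` is an undirected simple graph over string protein
identifiers, stored as a symmetric binary sparse adjacency matrix together
with an ordered node list.  Column-normalizing the adjacency yields the
transition matrix of the random walk used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PPINetwork",
    "TransitionMatrix",
    "EdgeListError",
    "load_edge_list",
    "parse_edges",
    "build_network",
    "column_normalize",
    "restrict_to_nodes",
    "write_edge_list",
]


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass(frozen=True)
class PPINetwork:
    """Undirected PPI graph with a fixed node ordering.

    Attributes
    ----------
    node_ids : tuple of str
        Unique protein identifiers; position defines the matrix index.
    adjacency : scipy.sparse.csr_matrix
        Symmetric binary matrix with zero diagonal.
    """

    node_ids: tuple[str, ...]
    adjacency: sp.csr_matrix
    _index: dict[str, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {v: i for i, v in enumerate(self.node_ids)}
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown protein identifier: {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) identifier pairs, deterministically ordered."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        pairs = [
            tuple(sorted((self.node_ids[i], self.node_ids[j])))
            for i, j in zip(coo.row, coo.col)
        ]
        return sorted(pairs)


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic sparse matrix driving the random walk."""

    matrix: sp.csr_matrix
    normalization: str = "column_stochastic"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def parse_edges(
    lines,
    delimiter: str | None = "\t",
    cols: tuple[int, int] = (0, 1),
    source: str = "<memory>",
) -> list[tuple[str, str]]:
    """Parse identifier pairs from an iterable of text lines.

    Blank lines and lines starting with ``#`` are skipped.  ``delimiter=None``
    splits on any whitespace.  ``cols`` selects the two identifier columns,
    which accommodates SIF-style files (``cols=(0, 2)``).
    """
    i, j = cols
    need = max(i, j) + 1
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(delimiter) if delimiter else line.split()
        if len(parts) < need:
            raise EdgeListError(
                f"{source}: line {lineno}: expected at least {need} columns, "
                f"got {len(parts)}: {line!r}"
            )
        u, v = parts[i].strip(), parts[j].strip()
        if not u or not v:
            raise EdgeListError(f"{source}: line {lineno}: empty identifier")
        edges.append((u, v))
    return edges


def build_network(
    edges: list[tuple[str, str]], drop_self_loops: bool = True
) -> PPINetwork:
    """Build a :class:`PPINetwork` from raw identifier pairs.

    Duplicate edges (either orientation) collapse to one; self-loops are
    removed when ``drop_self_loops`` is set, and nodes left without any
    partner are dropped — a protein appearing only in a removed self-loop is
    treated as having no interacting partners.
    """
    undirected = set()
    for u, v in edges:
        if u == v:
            if drop_self_loops:
                continue
            raise EdgeListError(f"self-loop on {u!r} with drop_self_loops=False")
        undirected.add((u, v) if u < v else (v, u))
    if not undirected:
        raise EdgeListError("no edges remain after filtering")
    nodes = sorted({u for e in undirected for u in e})
    index = {v: i for i, v in enumerate(nodes)}
    rows, colz = [], []
    for u, v in undirected:
        iu, iv = index[u], index[v]
        rows.extend((iu, iv))
        colz.extend((iv, iu))
    n = len(nodes)
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, colz)), shape=(n, n), dtype=float
    )
    return PPINetwork(node_ids=tuple(nodes), adjacency=adj)


def load_edge_list(
    path,
    delimiter: str | None = "\t",
    drop_self_loops: bool = True,
    cols: tuple[int, int] = (0, 1),
) -> PPINetwork:
    """Load an undirected PPI network from a two-column edge list file."""
    with open(path) as fh:
        edges = parse_edges(fh, delimiter=delimiter, cols=cols, source=str(path))
    if not edges:
        raise EdgeListError(f"{path}: no edges found")
    return build_network(edges, drop_self_loops=drop_self_loops)


def write_edge_list(net: PPINetwork, path) -> None:
    """Write the canonical edge list (sorted endpoints, sorted lines)."""
    with open(path, "w") as fh:
        for u, v in net.edges():
            fh.write(f"{u}\t{v}\n")


def column_normalize(net: PPINetwork) -> TransitionMatrix:
    """Degree-normalize the adjacency so that every column sums to one.

    Entry (i, j) becomes A_ij / deg(j): the probability that a walker at j
    steps to neighbor i.
    """
    deg = np.asarray(net.adjacency.sum(axis=0)).ravel()
    if np.any(deg == 0):
        bad = [net.node_ids[i] for i in np.flatnonzero(deg == 0)[:5]]
        raise ValueError(f"zero-degree nodes present: {bad}")
    w = net.adjacency @ sp.diags(1.0 / deg)
    return TransitionMatrix(matrix=w.tocsr())


def restrict_to_nodes(
    net: PPINetwork, keep
) -> tuple[PPINetwork, dict[str, list[str]]]:
    """Induced subgraph on ``keep``, dropping nodes it isolates.

    Returns the restricted network and a report dict with keys ``unknown``
    (requested ids absent from the network) and ``isolated`` (kept ids left
    without partners and therefore dropped).
    """
    keep = set(keep)
    known = [v for v in net.node_ids if v in keep]
    unknown = sorted(keep - set(net.node_ids))
    if not known:
        raise ValueError("no requested node is present in the network")
    idx = np.array([net.index_of(v) for v in known])
    sub = net.adjacency[np.ix_(idx, idx)]
    deg = np.asarray(sub.sum(axis=0)).ravel()
    alive = deg > 0
    isolated = [known[i] for i in np.flatnonzero(~alive)]
    if not alive.any():
        raise ValueError("restriction produced an empty network")
    sub = sub[np.ix_(np.flatnonzero(alive), np.flatnonzero(alive))]
    kept = tuple(v for v, a in zip(known, alive) if a)
    report = {"unknown": unknown, "isolated": sorted(isolated)}
    return PPINetwork(node_ids=kept, adjacency=sub.tocsr()), report
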