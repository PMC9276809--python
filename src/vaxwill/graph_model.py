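"""Social graph container and row-stochastic influence matrix.

The opinion dynamics run on an undirected, connected friendship graph in
which every agent also listens to itself: a self-loop is present at each
node, and the influence weight an agent assigns to each member of its
(self-inclusive) neighborhood :math:`N_i` is uniform,

.. math:: w_{ij} = 1/|N_i| \\quad (j \\in N_i), \\qquad w_{ij} = 0
          \\text{ otherwise},

so that :math:`W` is row-stochastic.  Self-loops are structural — they are
added by every constructor whether or not the input file lists them — and
are never written back out.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GraphFormatError",
    "GraphValidationError",
    "SocialNetwork",
    "build_row_stochastic",
    "load_edge_list",
    "write_edge_list",
]


class GraphFormatError(ValueError):
    """Raised when a graph file cannot be parsed."""


class GraphValidationError(ValueError):
    """Raised when a parsed graph violates a structural requirement."""


@dataclass(frozen=True)
class SocialNetwork:
    """Undirected social graph with self-loops and its influence matrix.

    Attributes
    ----------
    n:
        Number of agents, indexed ``0..n-1`` internally.
    adjacency:
        Boolean CSR adjacency *including* the structural self-loops, so
        row ``i`` marks the full neighborhood ``N_i``.
    W:
        Row-stochastic CSR influence matrix, ``w_ij = 1/|N_i|`` on ``N_i``.
    node_labels:
        Original node identifiers, ``node_labels[i]`` being the label of
        internal agent ``i``.  Kept so that target selections and reports
        are stable under relabeling of the input file.
    """

    n: int
    adjacency: sp.csr_array = field(repr=False)
    W: sp.csr_array = field(repr=False)
    node_labels: np.ndarray = field(repr=False)

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[int, int]],
        n: int | None = None,
        node_labels: Sequence | None = None,
    ) -> "SocialNetwork":
        """Build a network from undirected edges over ``0..n-1``.

        Self-loops in ``edges`` are ignored (they are implicit), duplicate
        edges are collapsed, and a self-loop is added to every node.  The
        graph must be connected and free of isolated nodes.
        """
        pairs = {(min(i, j), max(i, j)) for i, j in edges if i != j}
        if not pairs:
            raise GraphValidationError("graph has no non-self edges")
        arr = np.array(sorted(pairs), dtype=np.int64)
        if arr.min() < 0:
            raise GraphValidationError("negative node index in edge list")
        n_seen = int(arr.max()) + 1
        if n is None:
            n = n_seen
        elif n < n_seen:
            raise GraphValidationError(
                f"edge list references node {n_seen - 1} but n={n}"
            )
        rows = np.concatenate([arr[:, 0], arr[:, 1], np.arange(n)])
        cols = np.concatenate([arr[:, 1], arr[:, 0], np.arange(n)])
        adj = sp.csr_array(
            (np.ones(rows.size, dtype=bool), (rows, cols)), shape=(n, n)
        )
        deg = adj.sum(axis=1)  # |N_i|, self-loop included
        if np.any(deg < 2):
            isolated = np.flatnonzero(deg < 2)
            raise GraphValidationError(
                f"{isolated.size} isolated node(s), e.g. index {isolated[0]}"
            )
        ncomp, _ = connected_components(adj, directed=False)
        if ncomp != 1:
            raise GraphValidationError(
                f"graph is disconnected ({ncomp} components); "
                "the steady-state theory requires a connected graph"
            )
        W = _row_normalize(adj)
        if node_labels is None:
            node_labels = np.arange(n)
        labels = np.asarray(node_labels)
        if labels.shape != (n,):
            raise GraphValidationError("node_labels must have length n")
        return cls(n=n, adjacency=adj, W=W, node_labels=labels)

    # ------------------------------------------------------------------ #
    # derived views
    # ------------------------------------------------------------------ #
    @property
    def edges(self) -> set[tuple[int, int]]:
        """Set of unordered non-self edges as sorted index pairs."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return set(zip(coo.row.tolist(), coo.col.tolist()))

    @property
    def n_edges(self) -> int:
        """Number of undirected non-self edges."""
        return int(sp.triu(self.adjacency, k=1).nnz)

    @property
    def degrees(self) -> np.ndarray:
        """Non-self-loop degree of each agent (used for target ranking)."""
        return np.asarray(self.adjacency.sum(axis=1) - 1, dtype=np.int64)

    def neighborhoods(self) -> list[np.ndarray]:
        """Self-inclusive neighborhood ``N_i`` of every agent."""
        csr = self.adjacency
        return [
            csr.indices[csr.indptr[i] : csr.indptr[i + 1]].copy()
            for i in range(self.n)
        ]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


def _row_normalize(adj: sp.csr_array) -> sp.csr_array:
    deg = np.asarray(adj.sum(axis=1), dtype=float)
    W = adj.astype(float).multiply(1.0 / deg[:, None]).tocsr()
    return sp.csr_array(W)


def build_row_stochastic(neighborhoods: Sequence[Iterable[int]]) -> sp.csr_array:
    """Influence matrix ``w_ij = 1/|N_i|`` from explicit neighborhoods.

    Each ``neighborhoods[i]`` must contain agent ``i`` itself (the
    structural self-loop); rows are normalized by ``|N_i|`` exactly.
    """
    n = len(neighborhoods)
    rows, cols, vals = [], [], []
    for i, nbrs in enumerate(neighborhoods):
        nbrs = sorted(set(int(j) for j in nbrs))
        if not nbrs:
            raise GraphValidationError(f"neighborhood of agent {i} is empty")
        if i not in nbrs:
            raise GraphValidationError(
                f"agent {i} missing from its own neighborhood (no self-loop)"
            )
        if nbrs[0] < 0 or nbrs[-1] >= n:
            raise GraphValidationError(f"neighborhood of agent {i} out of range")
        w = 1.0 / len(nbrs)
        rows.extend([i] * len(nbrs))
        cols.extend(nbrs)
        vals.extend([w] * len(nbrs))
    return sp.csr_array((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------- #
# file I/O
# ---------------------------------------------------------------------- #
def load_edge_list(path: str | Path, format: str | None = None) -> SocialNetwork:
    """Read a social graph from an edge-list or Matrix Market file.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"edge-list"`` or ``"matrix-market"``; inferred from the file
        extension (``.mtx``) or a ``%%MatrixMarket`` banner when omitted.

    Notes
    -----
    Edge lists are two integer columns separated by whitespace or commas;
    lines starting with ``%`` or ``#`` are comments.  Arbitrary integer
    node labels are mapped to contiguous internal indices in sorted label
    order, and the mapping is kept on the returned network.  Self-loops
    are implicit and added regardless of the file contents.
    """
    path = Path(path)
    if not path.exists():
        raise GraphFormatError(f"no such file: {path}")
    if format is None:
        format = _sniff_format(path)
    if format == "matrix-market":
        return _load_matrix_market(path)
    if format == "edge-list":
        return _load_plain_edges(path)
    raise GraphFormatError(
        f"unknown format {format!r}; expected 'edge-list' or 'matrix-market'"
    )


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() == ".mtx":
        return "matrix-market"
    with open(path, "r") as fh:
        first = fh.readline()
    if first.startswith("%%MatrixMarket"):
        return "matrix-market"
    return "edge-list"


def _load_plain_edges(path: Path) -> SocialNetwork:
    raw_pairs: list[tuple[int, int]] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("%", "#")):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two columns, got {line!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise GraphFormatError(
                    f"{path}:{lineno}: non-integer node id in {line!r}"
                ) from exc
            raw_pairs.append((u, v))
    if not raw_pairs:
        raise GraphFormatError(f"{path}: no edges found")
    return _from_labeled_pairs(raw_pairs)


def _load_matrix_market(path: Path) -> SocialNetwork:
    try:
        mat = scipy.io.mmread(str(path))
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise GraphFormatError(f"{path}: Matrix Market parse failure: {exc}") from exc
    coo = sp.coo_array(mat)
    if coo.shape[0] != coo.shape[1]:
        raise GraphFormatError(f"{path}: adjacency matrix must be square")
    pairs = list(zip(coo.row.tolist(), coo.col.tolist()))
    if not pairs:
        raise GraphFormatError(f"{path}: matrix has no entries")
    n = coo.shape[0]
    # keep declared dimension so genuinely isolated rows are detected
    return _from_labeled_pairs(pairs, declared_labels=np.arange(n))


def _from_labeled_pairs(
    pairs: list[tuple[int, int]], declared_labels: np.ndarray | None = None
) -> SocialNetwork:
    if declared_labels is None:
        labels = np.unique(np.array(pairs, dtype=np.int64))
    else:
        labels = np.asarray(declared_labels, dtype=np.int64)
    index = {int(lab): i for i, lab in enumerate(labels)}
    try:
        edges = [(index[int(u)], index[int(v)]) for u, v in pairs]
    except KeyError as exc:
        raise GraphFormatError(f"node label {exc} outside declared range") from exc
    return SocialNetwork.from_edges(edges, n=len(labels), node_labels=labels)


def write_edge_list(net: SocialNetwork, path: str | Path) -> None:
    """Write the canonical edge list: sorted pairs, self-loops omitted."""
    buf = io.StringIO()
    for i, j in sorted(net.edges):
        buf.write(f"{net.node_labels[i]} {net.node_labels[j]}\n")
    Path(path).write_text(buf.getvalue())
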