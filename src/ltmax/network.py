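"""Immutable undirected simple-graph container and plain-text edge-list I/O."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np


class Network:
    """Undirected simple graph on integer nodes ``0 .. n_nodes - 1``.

    Edges are canonicalized to ``i < j`` and stored both as an ``(E, 2)``
    array and as a CSR adjacency (``indptr``/``indices``) so cascade kernels
    can traverse neighborhoods without Python overhead.  For undirected
    graphs the in- and out-degree coincide with ``degree``; the CSR layout
    stores each edge as two directed influence channels, which keeps a future
    directed-graph extension localized here.

    Instances are treated as immutable: operations that change topology
    (e.g. assortativity rewiring) return a new ``Network``.
    """

    __slots__ = ("n_nodes", "edges", "degree", "indptr", "indices")

    def __init__(self, n_nodes: int, edges) -> None:
        n_nodes = int(n_nodes)
        if n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= n_nodes:
                raise ValueError("edge endpoint outside node range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            edges = np.stack([lo, hi], axis=1)
            order = np.lexsort((edges[:, 1], edges[:, 0]))
            edges = edges[order]
            if edges.shape[0] > 1 and np.any(
                (edges[1:, 0] == edges[:-1, 0]) & (edges[1:, 1] == edges[:-1, 1])
            ):
                raise ValueError("duplicate edges are not allowed")
        self.n_nodes = n_nodes
        self.edges = edges
        self.degree = np.bincount(edges.ravel(), minlength=n_nodes).astype(np.int64)
        indptr = np.zeros(n_nodes + 1, dtype=np.int64)
        np.cumsum(self.degree, out=indptr[1:])
        self.indptr = indptr
        if edges.size:
            directed = np.concatenate([edges, edges[:, ::-1]])
            self.indices = directed[np.argsort(directed[:, 0], kind="stable"), 1].copy()
        else:
            self.indices = np.empty(0, dtype=np.int64)

    # -- basic queries -----------------------------------------------------

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- conversions -------------------------------------------------------

    @classmethod
    def from_networkx(cls, g: nx.Graph, n_nodes: int | None = None) -> "Network":
        n = n_nodes if n_nodes is not None else g.number_of_nodes()
        return cls(n, np.array(list(g.edges()), dtype=np.int64).reshape(-1, 2))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    # -- plain-text I/O ----------------------------------------------------

    @classmethod
    def read_edgelist(cls, path, n_nodes: int | None = None) -> "Network":
        """Read a whitespace-separated edge list (one ``i j`` pair per line,
        0-based ids).  Node count defaults to ``max id + 1``."""
        raw = Path(path).read_text().split()
        vals = np.array(raw, dtype=np.int64).reshape(-1, 2)
        if n_nodes is None:
            n_nodes = int(vals.max()) + 1 if vals.size else 1
        return cls(n_nodes, vals)

    def write_edgelist(self, path) -> None:
        """Write the canonical (``i < j``, sorted) tab-separated edge list."""
        with open(path, "w") as fh:
            for a, b in self.edges:
                fh.write(f"{a}\t{b}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)
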