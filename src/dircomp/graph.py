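"""Directed-graph data model, text I/O and structural primitives.

The :class:`DirectedGraph` is the substrate for every computation in this
package: a simple, unweighted digraph with opaque string node labels, no
self-loops and no parallel edges.  Reciprocal dyads (``u -> v`` together with
``v -> u``) are allowed and are what the ``reciprocal_degree`` column counts.

Node labels never leak an internal ordering: every public table is indexed by
label, and the dense integer indexing used by the motif census and the null
models is an implementation detail.
"""

from __future__ import annotations

import io
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedGraph",
    "GraphParseError",
    "read_edgelist",
    "read_graphml",
    "write_edgelist",
    "degree_vectors",
    "directed_clustering",
    "degree_dependent_clustering",
    "grouped_clustering",
    "shortest_path_lengths",
    "ClusteringTable",
]

_NODE_COMMENT = "# node:"


class GraphParseError(ValueError):
    """Raised for malformed edge-list input."""


class DirectedGraph:
    """Simple, unweighted, directed graph with string node labels.

    Parameters
    ----------
    nodes
        Iterable of node labels; order of first appearance is preserved.
        Endpoints of ``edges`` are added automatically.
    edges
        Iterable of ``(source, target)`` label pairs.  Duplicates collapse;
        self-loops raise ``ValueError``.
    """

    __slots__ = ("_nodes", "_index", "_edges", "_cache", "meta")

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        index: dict[str, int] = {}
        for u in nodes:
            u = str(u)
            if u not in index:
                index[u] = len(index)
        edge_set: set[tuple[str, str]] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed")
            for w in (u, v):
                if w not in index:
                    index[w] = len(index)
            edge_set.add((u, v))
        self._nodes: tuple[str, ...] = tuple(index)
        self._index = index
        self._edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        self._cache: dict[str, object] = {}
        self.meta: dict[str, object] = {}

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self._edges

    @property
    def N(self) -> int:
        return len(self._nodes)

    @property
    def M(self) -> int:
        return len(self._edges)

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self._edges

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self._edges == other._edges

    def __hash__(self) -> int:  # labels + edges, order-free
        return hash((frozenset(self._nodes), self._edges))

    def __repr__(self) -> str:
        return f"DirectedGraph(N={self.N}, M={self.M})"

    # -- integer views (cached; graphs are immutable) ----------------------
    def successors_int(self) -> list[list[int]]:
        """Adjacency lists over dense integer node ids (label order)."""
        key = "succ_int"
        if key not in self._cache:
            succ: list[list[int]] = [[] for _ in self._nodes]
            idx = self._index
            for u, v in self._edges:
                succ[idx[u]].append(idx[v])
            for lst in succ:
                lst.sort()
            self._cache[key] = succ
        return self._cache[key]  # type: ignore[return-value]

    def bitmask_adjacency(self) -> tuple[list[int], list[int]]:
        """``(out, und)`` bitmask adjacency: bit ``j`` of ``out[i]`` is the
        edge ``i -> j``; ``und`` is the weak (symmetrized) adjacency."""
        key = "bitmasks"
        if key not in self._cache:
            n = self.N
            out = [0] * n
            und = [0] * n
            idx = self._index
            for u, v in self._edges:
                i, j = idx[u], idx[v]
                out[i] |= 1 << j
                und[i] |= 1 << j
                und[j] |= 1 << i
            self._cache[key] = (out, und)
        return self._cache[key]  # type: ignore[return-value]

    def adjacency_matrix(self, dtype=np.int8) -> np.ndarray:
        """Dense asymmetric adjacency matrix ``A`` in node order."""
        A = np.zeros((self.N, self.N), dtype=dtype)
        idx = self._index
        for u, v in self._edges:
            A[idx[u], idx[v]] = 1
        return A

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    def relabel(self, mapping: Mapping[str, str]) -> "DirectedGraph":
        """Return an isomorphic copy with nodes renamed through ``mapping``."""
        return DirectedGraph(
            nodes=[mapping.get(u, u) for u in self._nodes],
            edges=[(mapping.get(u, u), mapping.get(v, v)) for u, v in self._edges],
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edgelist(source) -> DirectedGraph:
    """Read a tab-separated edge list.

    One ``source<TAB>target`` pair per line.  Lines starting with ``#`` are
    comments, except ``# node: LABEL`` which declares a (possibly isolated)
    node.  Duplicate edges collapse; self-loop lines are dropped with a
    warning and counted in ``graph.meta['self_loops_dropped']``.

    ``source`` may be a path or an open text stream.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, "r", encoding="utf-8") as fh:
            return read_edgelist(fh)
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    self_loops = 0
    n_lines = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        n_lines += 1
        if line.startswith("#"):
            if line.startswith(_NODE_COMMENT):
                nodes.append(line[len(_NODE_COMMENT):].strip())
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise GraphParseError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        u, v = fields
        if u == v:
            self_loops += 1
            continue
        edges.append((u, v))
    if n_lines == 0:
        raise GraphParseError("empty input: no nodes or edges found")
    if self_loops:
        logger.warning("dropped %d self-loop line(s)", self_loops)
    g = DirectedGraph(nodes=nodes, edges=edges)
    g.meta["self_loops_dropped"] = self_loops
    return g


def read_graphml(source) -> DirectedGraph:
    """Read a directed GraphML file (read-only interchange format)."""
    import networkx as nx

    g = nx.read_graphml(source)
    if not g.is_directed():
        raise GraphParseError("GraphML input is not a directed graph")
    edges = [(str(u), str(v)) for u, v in g.edges() if str(u) != str(v)]
    return DirectedGraph(nodes=[str(u) for u in g.nodes()], edges=edges)


def write_edgelist(G: DirectedGraph, sink) -> None:
    """Write ``G`` as a deterministic tab-separated edge list.

    Edges are sorted lexicographically; isolated nodes are declared through
    ``# node:`` header comments so that read/write round-trips exactly.
    """
    if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
        with open(sink, "w", encoding="utf-8") as fh:
            write_edgelist(G, fh)
            return
    linked = {u for e in G.edges for u in e}
    for u in sorted(set(G.nodes) - linked):
        sink.write(f"{_NODE_COMMENT} {u}\n")
    for u, v in sorted(G.edges):
        sink.write(f"{u}\t{v}\n")


def to_edgelist_text(G: DirectedGraph) -> str:
    buf = io.StringIO()
    write_edgelist(G, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# degrees
# ---------------------------------------------------------------------------

def degree_vectors(G: DirectedGraph) -> pd.DataFrame:
    """Per-node degree table.

    Columns: ``in_degree``, ``out_degree``, ``total_degree`` (their sum) and
    ``reciprocal_degree`` (number of partners connected in both directions).
    """
    idx = {u: i for i, u in enumerate(G.nodes)}
    ind = np.zeros(G.N, dtype=np.int64)
    outd = np.zeros(G.N, dtype=np.int64)
    recip = np.zeros(G.N, dtype=np.int64)
    for u, v in G.edges:
        outd[idx[u]] += 1
        ind[idx[v]] += 1
        if (v, u) in G.edges:
            recip[idx[u]] += 1
    return pd.DataFrame(
        {
            "in_degree": ind,
            "out_degree": outd,
            "total_degree": ind + outd,
            "reciprocal_degree": recip,
        },
        index=list(G.nodes),
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringTable:
    """Per-node directed clustering coefficients and their degree profile.

    ``per_node`` maps node label to the all-triangle directed clustering
    coefficient

        C_i = [(A + A^T)^3]_ii / (2 [d_tot (d_tot - 1) - 2 d_recip]),

    which counts every directed triangle configuration through node *i*
    against the number of possible ones; the coefficient is defined as 0
    whenever the denominator vanishes.  ``by_degree`` is the degree-dependent
    clustering curve: the arithmetic mean of C_i over the nodes of each total
    degree present in the graph.
    """

    per_node: pd.Series
    by_degree: pd.Series = field(default=None)  # type: ignore[assignment]


def _clustering_arrays(B: np.ndarray, dtot: np.ndarray) -> np.ndarray:
    num = np.einsum("ij,jk,ki->i", B, B, B, optimize=True).astype(float)
    recip = (B == 2).sum(axis=1)
    denom = 2.0 * (dtot * (dtot - 1.0) - 2.0 * recip)
    out = np.zeros(len(dtot))
    mask = denom > 0
    out[mask] = num[mask] / denom[mask]
    return out


def directed_clustering(G: DirectedGraph) -> ClusteringTable:
    """All-triangle directed clustering coefficient of every node."""
    A = G.adjacency_matrix(dtype=np.float64)
    B = A + A.T
    dtot = B.sum(axis=1)  # in + out degree (reciprocal partners count twice)
    coeffs = _clustering_arrays(B, dtot)
    per_node = pd.Series(coeffs, index=list(G.nodes), name="clustering")
    table = ClusteringTable(per_node=per_node)
    table.by_degree = _group_by_degree(coeffs, dtot.astype(int))
    return table


def _group_by_degree(coeffs: np.ndarray, dtot: np.ndarray) -> pd.Series:
    ks = np.unique(dtot)
    means = [coeffs[dtot == k].mean() for k in ks]
    return pd.Series(means, index=ks, name="mean_clustering")


def degree_dependent_clustering(G: DirectedGraph) -> pd.Series:
    """Degree-dependent clustering curve c̄(k) of ``G``.

    Maps each total degree k present in the graph to the mean directed
    clustering coefficient over exactly the nodes of that degree.
    """
    return directed_clustering(G).by_degree


def grouped_clustering(degrees: Iterable[int], coefficients: Iterable[float]) -> pd.Series:
    """c̄(k) from printed per-node degree and coefficient lists."""
    d = np.asarray(list(degrees), dtype=int)
    c = np.asarray(list(coefficients), dtype=float)
    if d.shape != c.shape:
        raise ValueError("degrees and coefficients must have equal length")
    return _group_by_degree(c, d)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def shortest_path_lengths(G: DirectedGraph, source: str) -> dict[str, int]:
    """Directed BFS distances from ``source``.

    Unreachable nodes are absent from the result; ``result[source] == 0``.
    """
    if source not in G:
        raise KeyError(f"unknown source node {source!r}")
    idx = {u: i for i, u in enumerate(G.nodes)}
    succ = G.successors_int()
    dist = {idx[source]: 0}
    q = deque([idx[source]])
    while q:
        x = q.popleft()
        for y in succ[x]:
            if y not in dist:
                dist[y] = dist[x] + 1
                q.append(y)
    labels = G.nodes
    return {labels[i]: d for i, d in dist.items()}


def all_pairs_distance_matrix(G: DirectedGraph) -> np.ndarray:
    """N x N matrix of directed BFS distances (np.inf where unreachable),
    rows/columns in node order."""
    n = G.N
    succ = G.successors_int()
    D = np.full((n, n), np.inf)
    for s in range(n):
        dist = {s: 0}
        q = deque([s])
        while q:
            x = q.popleft()
            for y in succ[x]:
                if y not in dist:
                    dist[y] = dist[x] + 1
                    q.append(y)
        for j, d in dist.items():
            D[s, j] = d
    return D
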