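"""Baseline directed-network dissimilarities: portrait, DeltaCon, closeness.

Three classical comparison measures used as references for the motif-based
dissimilarity:

* **Portrait divergence Dp** — compares the matrices ``B[l, k]`` counting
  nodes that see exactly k nodes at directed shortest-path distance l.
* **DeltaCon distance Dd** — Frobenius distance of the attenuated-propagation
  node-affinity matrices ``S = (I + eps^2 D - eps A)^{-1}``.
* **Closeness distance Dc** — L1 distance of the directed closeness
  centrality vectors.

Dd and Dc compare node-aligned quantities and therefore require the two
graphs to share an identical labeled node set (the benchmarks only ever
compare a graph with its own null-model or perturbed variants); Dp is
label-free and accepts graphs of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import DirectedGraph, all_pairs_distance_matrix, degree_vectors

__all__ = [
    "Portrait",
    "portrait",
    "portrait_divergence",
    "similarity_matrix",
    "deltacon_distance",
    "closeness_centrality",
    "closeness_distance",
    "ComparabilityError",
]


class ComparabilityError(ValueError):
    """The two graphs do not share the node set a baseline requires."""


def _check_same_nodes(G1: DirectedGraph, G2: DirectedGraph) -> list[str]:
    s1, s2 = set(G1.nodes), set(G2.nodes)
    if s1 != s2:
        offending = sorted(s1 ^ s2)
        raise ComparabilityError(
            f"graphs must share an identical labeled node set; "
            f"mismatched labels: {offending[:10]}"
        )
    return sorted(s1)


@dataclass(frozen=True)
class Portrait:
    """Distance-histogram portrait of a digraph.

    ``B[l, k]`` (rows ``l = 0..d``, columns ``k = 0..N-1``) counts the nodes
    that have exactly k nodes at directed distance l; d is the directed
    diameter over reachable pairs.  Every row sums to N — a node with no
    nodes at distance l lands in the k = 0 bin; unreachable pairs contribute
    to no distance row.  The row-normalized form Q = B / N is row-stochastic.
    """

    B: np.ndarray

    @property
    def Q(self) -> np.ndarray:
        return self.B / self.B[0].sum()

    @property
    def diameter(self) -> int:
        return self.B.shape[0] - 1


def portrait(G: DirectedGraph) -> Portrait:
    """Build the shortest-path portrait of ``G`` from per-source BFS."""
    if G.N < 1:
        raise ValueError("portrait of an empty graph is undefined")
    D = all_pairs_distance_matrix(G)
    finite = np.isfinite(D)
    d = int(D[finite].max()) if finite.any() else 0
    n = G.N
    B = np.zeros((d + 1, n), dtype=np.int64)
    for l in range(d + 1):
        counts_per_node = (D == l).sum(axis=1)  # includes self at l = 0
        for c in counts_per_node:
            B[l, int(c)] += 1
    return Portrait(B=B)


def _flatten_portrait(P: Portrait, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad Q to ``shape`` and scale to a single probability vector.

    Each row of Q sums to 1, so dividing the padded matrix by the original
    row count gives a distribution over (distance, count) cells.
    """
    Q = P.Q
    out = np.zeros(shape)
    out[: Q.shape[0], : Q.shape[1]] = Q
    return (out / Q.shape[0]).ravel()


def portrait_divergence(G1: DirectedGraph, G2: DirectedGraph) -> float:
    """Portrait divergence Dp between two digraphs (nats, in [0, ln 2]).

    Jensen-Shannon divergence of the two flattened portrait distributions;
    graphs may differ in size and labels.
    """
    P1, P2 = portrait(G1), portrait(G2)
    shape = (
        max(P1.B.shape[0], P2.B.shape[0]),
        max(P1.B.shape[1], P2.B.shape[1]),
    )
    p = _flatten_portrait(P1, shape)
    q = _flatten_portrait(P2, shape)
    m = 0.5 * (p + q)
    safe_m = np.where(m > 0, m, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = np.where(p > 0, p * np.log(p / safe_m), 0.0).sum()
        kl_q = np.where(q > 0, q * np.log(q / safe_m), 0.0).sum()
    return max(0.0, float(0.5 * kl_p + 0.5 * kl_q))


def similarity_matrix(G: DirectedGraph, node_order=None) -> np.ndarray:
    """DeltaCon node-affinity matrix ``S = (I + eps^2 D - eps A)^{-1}``.

    D is the diagonal of total degrees and ``eps = 1 / (1 + max total
    degree)``, which keeps the linear system well conditioned; S = I for an
    edgeless graph.
    """
    order = list(node_order) if node_order is not None else list(G.nodes)
    idx = {u: i for i, u in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for u, v in G.edges:
        A[idx[u], idx[v]] = 1.0
    dtot = A.sum(axis=0) + A.sum(axis=1)
    eps = 1.0 / (1.0 + (dtot.max() if n else 0.0))
    lhs = np.eye(n) + eps**2 * np.diag(dtot) - eps * A
    return np.linalg.solve(lhs, np.eye(n))


def deltacon_distance(G1: DirectedGraph, G2: DirectedGraph) -> float:
    """DeltaCon distance Dd: Frobenius distance of the two affinity matrices.

    Requires identical labeled node sets so the matrices align entrywise.
    """
    order = _check_same_nodes(G1, G2)
    S1 = similarity_matrix(G1, order)
    S2 = similarity_matrix(G2, order)
    return float(np.sqrt(((S1 - S2) ** 2).sum()))


def closeness_centrality(G: DirectedGraph) -> dict[str, float]:
    """Directed closeness ``c_i = 1 / sum_j d_ij`` over reachable ``j != i``;
    0 for nodes that reach nothing."""
    D = all_pairs_distance_matrix(G)
    np.fill_diagonal(D, np.inf)
    out: dict[str, float] = {}
    for i, u in enumerate(G.nodes):
        row = D[i][np.isfinite(D[i])]
        out[u] = float(1.0 / row.sum()) if row.size else 0.0
    return out


def closeness_distance(G1: DirectedGraph, G2: DirectedGraph) -> float:
    """Closeness distance Dc: L1 distance of label-aligned closeness vectors."""
    order = _check_same_nodes(G1, G2)
    c1 = closeness_centrality(G1)
    c2 = closeness_centrality(G2)
    return float(sum(abs(c1[u] - c2[u]) for u in order))
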