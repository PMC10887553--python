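"""Synthetic digraph generators and named toy fixtures.

These supply every input the tests and experiments use: Erdős–Rényi
digraphs as stand-ins for real networks, simple parametric families
(cycles, paths, stars, the mutual dyad), and a 9-node toy whose
total-degree sequence {2,3,3,3,3,1,1,1,1} and per-node clustering
coefficients {1/2, 1/6, 0, 0, 1/6, 0, 0, 0, 0} give the degree-dependent
clustering curve {1: 0, 2: 1/2, 3: 1/12} used to illustrate the Dk2.5
null model.
"""

from __future__ import annotations

import numpy as np

from .graph import DirectedGraph

__all__ = [
    "generate_er_digraph",
    "directed_cycle",
    "directed_path",
    "out_star",
    "in_star",
    "mutual_dyad",
    "clustered_toy9",
    "toy_fixtures",
]


def _labels(n: int) -> list[str]:
    width = len(str(max(n - 1, 0)))
    return [f"n{str(i).zfill(width)}" for i in range(n)]


def generate_er_digraph(
    n: int,
    p: float | None = None,
    m: int | None = None,
    seed: int | None = None,
) -> DirectedGraph:
    """Erdős–Rényi digraph: G(n, p) or G(n, m).

    With ``p``, each of the n(n-1) ordered non-self pairs is an edge
    independently with probability p; with ``m``, exactly m distinct ordered
    pairs are drawn uniformly.  Exactly one of ``p`` and ``m`` must be given.
    """
    if (p is None) == (m is None):
        raise ValueError("give exactly one of p or m")
    rng = np.random.default_rng(seed)
    labels = _labels(n)
    if p is not None:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {p}")
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        pairs = np.argwhere(mask)
    else:
        capacity = n * (n - 1)
        if not 0 <= m <= capacity:
            raise ValueError(f"m must lie in [0, {capacity}], got {m}")
        # sample flat indices over ordered pairs, skipping the diagonal
        chosen = rng.choice(capacity, size=m, replace=False)
        rows = chosen // (n - 1)
        cols = chosen % (n - 1)
        cols = cols + (cols >= rows)  # shift to skip the self-loop slot
        pairs = np.stack([rows, cols], axis=1)
    edges = [(labels[int(i)], labels[int(j)]) for i, j in pairs]
    return DirectedGraph(nodes=labels, edges=edges)


def directed_cycle(n: int) -> DirectedGraph:
    """Directed cycle C_n (vertex-transitive; DNND is exactly 0)."""
    labels = _labels(n)
    return DirectedGraph(
        nodes=labels, edges=[(labels[i], labels[(i + 1) % n]) for i in range(n)]
    )


def directed_path(n: int) -> DirectedGraph:
    labels = _labels(n)
    return DirectedGraph(
        nodes=labels, edges=[(labels[i], labels[i + 1]) for i in range(n - 1)]
    )


def out_star(n: int) -> DirectedGraph:
    """Center with n-1 out-going spokes."""
    labels = _labels(n)
    return DirectedGraph(
        nodes=labels, edges=[(labels[0], labels[i]) for i in range(1, n)]
    )


def in_star(n: int) -> DirectedGraph:
    labels = _labels(n)
    return DirectedGraph(
        nodes=labels, edges=[(labels[i], labels[0]) for i in range(1, n)]
    )


def mutual_dyad() -> DirectedGraph:
    return DirectedGraph(edges=[("a", "b"), ("b", "a")])


def clustered_toy9() -> DirectedGraph:
    """9-node, 9-edge digraph with one directed triangle hanging off trees.

    Total-degree sequence (v1..v9) is {2,3,3,3,3,1,1,1,1} with per-node
    clustering {1/2, 1/6, 0, 0, 1/6, 0, 0, 0, 0}, hence degree-dependent
    clustering {1: 0, 2: 1/2, 3: 1/12}.  Contains the edges (v1,v2) and
    (v4,v3) whose double swap to (v1,v3), (v4,v2) preserves that curve.
    """
    edges = [
        ("v1", "v2"),
        ("v5", "v1"),
        ("v2", "v5"),
        ("v5", "v3"),
        ("v4", "v3"),
        ("v2", "v6"),
        ("v3", "v7"),
        ("v4", "v8"),
        ("v4", "v9"),
    ]
    return DirectedGraph(nodes=[f"v{i}" for i in range(1, 10)], edges=edges)


def toy_fixtures() -> dict[str, DirectedGraph]:
    """Named toy graphs used across tests and examples."""
    return {
        "cycle5": directed_cycle(5),
        "cycle3": directed_cycle(3),
        "path3": directed_path(3),
        "out_star4": out_star(4),
        "in_star4": in_star(4),
        "mutual_dyad": mutual_dyad(),
        "clustered9": clustered_toy9(),
    }
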