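"""Directed dk-series null models and the edge-perturbation generator.

The dk hierarchy randomizes a digraph while preserving progressively more
structure:

* **Dk1.0** — double-edge swaps ``(u->v, x->y) => (u->y, x->v)`` preserve
  every node's in- and out-degree.
* **Dk2.0** — the same swaps, additionally restricted to endpoint pairs in
  the same (in-degree, out-degree) class, which also preserves the joint
  degree distribution over edges.
* **Dk2.5** — a chain of Dk2.0-legal swaps driven by simulated annealing on
  the L1 discrepancy between the current and original degree-dependent
  clustering curves, so the clustering profile is preserved as well.

By default a strict-novelty rule is enforced: an accepted swap may not
re-create an edge of the *original* input graph.  Dense graphs can make this
constraint infeasible; the chain then stops at its attempt budget and the
report flags the shortfall instead of raising.

``perturb`` adds or removes a signed fraction ``f`` of the edges uniformly
at random, the protocol used to benchmark comparison methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import DirectedGraph, degree_vectors

__all__ = [
    "RewireReport",
    "PerturbationSpec",
    "dk1_rewire",
    "dk2_rewire",
    "dk25_rewire",
    "perturb",
]

DEFAULT_SWAP_MULTIPLE = 10  # accepted swaps per edge; standard mixing heuristic
_ATTEMPT_FACTOR = 100  # attempt budget per requested accepted swap


class _PairStream:
    """Buffered stream of random index pairs (and uniforms) from one rng."""

    def __init__(self, rng: np.random.Generator, m: int, chunk: int = 1 << 14):
        self.rng = rng
        self.m = m
        self.chunk = chunk
        self._pairs = np.empty((0, 2), dtype=np.int64)
        self._pos = 0

    def next_pair(self) -> tuple[int, int]:
        if self._pos >= len(self._pairs):
            self._pairs = self.rng.integers(self.m, size=(self.chunk, 2))
            self._pos = 0
        a, b = self._pairs[self._pos]
        self._pos += 1
        return int(a), int(b)


@dataclass
class RewireReport:
    """Provenance of one null-model realization."""

    model: str
    seed: int | None
    swaps_attempted: int
    swaps_accepted: int
    target_swaps: int
    strict_novelty: bool
    target_reached: bool
    conservation_checks: dict[str, bool] = field(default_factory=dict)
    clustering_l1: float | None = None
    within_tolerance: bool | None = None

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "seed": self.seed,
            "swaps_attempted": self.swaps_attempted,
            "swaps_accepted": self.swaps_accepted,
            "target_swaps": self.target_swaps,
            "strict_novelty": self.strict_novelty,
            "target_reached": self.target_reached,
            "conservation_checks": self.conservation_checks,
            "clustering_l1": self.clustering_l1,
            "within_tolerance": self.within_tolerance,
        }


@dataclass
class PerturbationSpec:
    """Provenance of one edge-perturbation realization."""

    f: float
    seed: int | None
    M_before: int
    M_after: int


def _int_edges(G: DirectedGraph) -> tuple[list[tuple[int, int]], dict[str, int]]:
    idx = {u: i for i, u in enumerate(G.nodes)}
    return [(idx[u], idx[v]) for u, v in sorted(G.edges)], idx


def _graph_from_int_edges(G: DirectedGraph, edges) -> DirectedGraph:
    labels = G.nodes
    return DirectedGraph(
        nodes=labels, edges=[(labels[i], labels[j]) for i, j in edges]
    )


def _joint_degree_histogram(G: DirectedGraph) -> dict:
    """Multiset of ((in,out) of source, (in,out) of target) over edges."""
    deg = degree_vectors(G)
    cls = {
        u: (int(deg.at[u, "in_degree"]), int(deg.at[u, "out_degree"]))
        for u in G.nodes
    }
    hist: dict = {}
    for u, v in G.edges:
        key = (cls[u], cls[v])
        hist[key] = hist.get(key, 0) + 1
    return hist


def _conservation_checks(G: DirectedGraph, H: DirectedGraph, joint: bool) -> dict[str, bool]:
    dg, dh = degree_vectors(G), degree_vectors(H)
    checks = {
        "node_set": set(G.nodes) == set(H.nodes),
        "edge_count": G.M == H.M,
        "in_degrees": dg["in_degree"].equals(dh["in_degree"].reindex(dg.index)),
        "out_degrees": dg["out_degree"].equals(dh["out_degree"].reindex(dg.index)),
    }
    if joint:
        checks["joint_degree_histogram"] = (
            _joint_degree_histogram(G) == _joint_degree_histogram(H)
        )
    return checks


def _swap_chain(
    G: DirectedGraph,
    model: str,
    swap_multiple: float,
    seed: int | None,
    strict_novelty: bool,
    same_class: bool,
) -> tuple[DirectedGraph, RewireReport]:
    if G.M < 2:
        report = RewireReport(
            model=model,
            seed=seed,
            swaps_attempted=0,
            swaps_accepted=0,
            target_swaps=0,
            strict_novelty=strict_novelty,
            target_reached=True,
            conservation_checks=_conservation_checks(G, G, joint=same_class),
        )
        return G, report
    rng = np.random.default_rng(seed)
    edges, _ = _int_edges(G)
    edge_set = set(edges)
    original = frozenset(edge_set)
    m = len(edges)
    if same_class:
        deg = degree_vectors(G)
        order = {u: i for i, u in enumerate(G.nodes)}
        cls = [0] * G.N
        for u in G.nodes:
            cls[order[u]] = (int(deg.at[u, "in_degree"]), int(deg.at[u, "out_degree"]))
    target = int(round(swap_multiple * m))
    budget = max(1000, _ATTEMPT_FACTOR * target)
    attempts = accepted = 0
    stream = _PairStream(rng, m)
    while accepted < target and attempts < budget:
        attempts += 1
        a, b = stream.next_pair()
        if a == b:
            continue
        u, v = edges[a]
        x, y = edges[b]
        if u == y or x == v:
            continue  # would create a self-loop
        new1, new2 = (u, y), (x, v)
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        if strict_novelty and (new1 in original or new2 in original):
            continue
        if same_class and not (cls[v] == cls[y] or cls[u] == cls[x]):
            continue
        edge_set.discard((u, v))
        edge_set.discard((x, y))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[a], edges[b] = new1, new2
        accepted += 1
    H = _graph_from_int_edges(G, edge_set)
    report = RewireReport(
        model=model,
        seed=seed,
        swaps_attempted=attempts,
        swaps_accepted=accepted,
        target_swaps=target,
        strict_novelty=strict_novelty,
        target_reached=accepted >= target,
        conservation_checks=_conservation_checks(G, H, joint=same_class),
    )
    return H, report


def dk1_rewire(
    G: DirectedGraph,
    swap_multiple: float = DEFAULT_SWAP_MULTIPLE,
    seed: int | None = None,
    strict_novelty: bool = True,
) -> tuple[DirectedGraph, RewireReport]:
    """Degree-preserving randomization (Dk1.0).

    Performs ``swap_multiple * M`` accepted double-edge swaps; every node
    keeps its in- and out-degree.  With ``strict_novelty`` (default) no new
    edge may duplicate an edge of the original graph.
    """
    return _swap_chain(G, "dk1.0", swap_multiple, seed, strict_novelty, same_class=False)


def dk2_rewire(
    G: DirectedGraph,
    swap_multiple: float = DEFAULT_SWAP_MULTIPLE,
    seed: int | None = None,
    strict_novelty: bool = True,
) -> tuple[DirectedGraph, RewireReport]:
    """Joint-degree-preserving randomization (Dk2.0).

    Like Dk1.0 but a swap is only legal when the two targets (or the two
    sources) have identical (in-degree, out-degree) pairs, which preserves
    the joint degree distribution over edges in addition to the degree
    sequences.
    """
    return _swap_chain(G, "dk2.0", swap_multiple, seed, strict_novelty, same_class=True)


# ---------------------------------------------------------------------------
# Dk2.5: annealed swaps preserving the degree-dependent clustering curve
# ---------------------------------------------------------------------------

class _ClusteringEnergy:
    """L1 distance of the degree-dependent clustering curve to a target.

    Operates on the dense symmetrized adjacency ``B = A + A^T`` (entries 0,
    1 or 2); degrees never change along a dk chain, so the degree grouping
    is fixed once.
    """

    def __init__(self, B: np.ndarray):
        self.B = B
        self.dtot = B.sum(axis=1).astype(float)
        ks, inverse = np.unique(self.dtot.astype(int), return_inverse=True)
        self.group = inverse
        self.group_sizes = np.bincount(inverse).astype(float)
        self.n_groups = len(ks)
        self.target = self.curve()

    def coefficients(self) -> np.ndarray:
        B = self.B
        num = ((B @ B) * B).sum(axis=1)  # diag of B^3; B is symmetric
        recip = (B == 2).sum(axis=1)
        denom = 2.0 * (self.dtot * (self.dtot - 1.0) - 2.0 * recip)
        c = np.zeros(len(B))
        mask = denom > 0
        c[mask] = num[mask] / denom[mask]
        return c

    def curve(self) -> np.ndarray:
        sums = np.bincount(self.group, weights=self.coefficients(), minlength=self.n_groups)
        return sums / self.group_sizes

    def energy(self) -> float:
        return float(np.abs(self.curve() - self.target).sum())

    def apply_swap(self, u: int, v: int, x: int, y: int, sign: int) -> None:
        B = self.B
        B[u, v] -= sign
        B[v, u] -= sign
        B[x, y] -= sign
        B[y, x] -= sign
        B[u, y] += sign
        B[y, u] += sign
        B[x, v] += sign
        B[v, x] += sign


def dk25_rewire(
    G: DirectedGraph,
    sweeps: int = 10,
    seed: int | None = None,
    initial_temperature: float = 0.01,
    cooling: float = 0.995,
    tolerance: float = 0.05,
    strict_novelty: bool = True,
    repair_sweeps: int = 20,
) -> tuple[DirectedGraph, RewireReport]:
    """Clustering-preserving randomization (Dk2.5).

    Runs ``sweeps`` sweeps of M Dk2.0-legal swap proposals each, accepted by
    the Metropolis rule on the L1 discrepancy E between the current and the
    original degree-dependent clustering curves (downhill always, uphill with
    probability ``exp(-dE / T)``, T cooled geometrically per sweep).  After
    annealing, greedy downhill sweeps run until ``E <= tolerance`` or
    ``repair_sweeps`` is exhausted; the report records the final E and
    whether it is within tolerance.  ``sweeps=0`` returns the input graph.
    """
    if G.M < 2 or sweeps == 0:
        report = RewireReport(
            model="dk2.5",
            seed=seed,
            swaps_attempted=0,
            swaps_accepted=0,
            target_swaps=0,
            strict_novelty=strict_novelty,
            target_reached=True,
            conservation_checks=_conservation_checks(G, G, joint=True),
            clustering_l1=0.0,
            within_tolerance=True,
        )
        return G, report
    rng = np.random.default_rng(seed)
    edges, _ = _int_edges(G)
    edge_set = set(edges)
    original = frozenset(edge_set)
    m = len(edges)
    deg = degree_vectors(G)
    order = {u: i for i, u in enumerate(G.nodes)}
    cls = [0] * G.N
    for u in G.nodes:
        cls[order[u]] = (int(deg.at[u, "in_degree"]), int(deg.at[u, "out_degree"]))

    A = G.adjacency_matrix(dtype=np.float64)
    state = _ClusteringEnergy(A + A.T)
    energy = 0.0
    temperature = initial_temperature
    attempts = accepted = 0
    proposal_cap = _ATTEMPT_FACTOR * m  # draw budget per sweep
    stream = _PairStream(rng, m)

    def run_sweep(temp: float | None) -> None:
        """One sweep of m legal proposals; temp=None means greedy only."""
        nonlocal energy, attempts, accepted
        legal = 0
        draws = 0
        while legal < m and draws < proposal_cap:
            draws += 1
            attempts += 1
            a, b = stream.next_pair()
            if a == b:
                continue
            u, v = edges[a]
            x, y = edges[b]
            if u == y or x == v:
                continue
            new1, new2 = (u, y), (x, v)
            if new1 in edge_set or new2 in edge_set or new1 == new2:
                continue
            if strict_novelty and (new1 in original or new2 in original):
                continue
            if not (cls[v] == cls[y] or cls[u] == cls[x]):
                continue
            legal += 1
            state.apply_swap(u, v, x, y, +1)
            new_energy = state.energy()
            d_e = new_energy - energy
            accept = d_e <= 0 or (
                temp is not None
                and temp > 0
                and rng.random() < math.exp(-d_e / temp)
            )
            if accept:
                energy = new_energy
                edge_set.discard((u, v))
                edge_set.discard((x, y))
                edge_set.add(new1)
                edge_set.add(new2)
                edges[a], edges[b] = new1, new2
                accepted += 1
            else:
                state.apply_swap(u, v, x, y, -1)

    for _ in range(sweeps):
        run_sweep(temperature)
        temperature *= cooling
    repairs = 0
    while energy > tolerance and repairs < repair_sweeps:
        before = energy
        run_sweep(None)
        repairs += 1
        if energy >= before - 1e-12:  # stuck in a local minimum
            break

    H = _graph_from_int_edges(G, edge_set)
    report = RewireReport(
        model="dk2.5",
        seed=seed,
        swaps_attempted=attempts,
        swaps_accepted=accepted,
        target_swaps=sweeps * m,
        strict_novelty=strict_novelty,
        target_reached=True,
        conservation_checks=_conservation_checks(G, H, joint=True),
        clustering_l1=energy,
        within_tolerance=energy <= tolerance,
    )
    return H, report


# ---------------------------------------------------------------------------
# edge perturbation
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5))


def perturb(
    G: DirectedGraph, f: float, seed: int | None = None
) -> tuple[DirectedGraph, PerturbationSpec]:
    """Randomly add (f > 0) or remove (f < 0) a ``|f|`` fraction of edges.

    Additions are drawn uniformly without replacement from the absent
    non-self-loop ordered pairs, removals uniformly from the existing edges;
    the node set is unchanged.  ``|f|`` must not exceed 0.9, mirroring the
    perturbation protocol's range.
    """
    if not -0.9 <= f <= 0.9:
        raise ValueError(f"f must lie in [-0.9, 0.9], got {f}")
    rng = np.random.default_rng(seed)
    delta = _round_half_away(f * G.M)
    edges, _ = _int_edges(G)
    n = G.N
    if f >= 0:
        if delta:
            present = np.zeros((n, n), dtype=bool)
            for i, j in edges:
                present[i, j] = True
            np.fill_diagonal(present, True)
            absent = np.flatnonzero(~present.ravel())
            if delta > len(absent):
                raise ValueError(
                    f"cannot add {delta} edges: only {len(absent)} absent pairs"
                )
            chosen = rng.choice(absent, size=delta, replace=False)
            edges = edges + [(int(c) // n, int(c) % n) for c in chosen]
    else:
        keep = rng.choice(len(edges), size=len(edges) - delta, replace=False)
        edges = [edges[i] for i in sorted(keep)]
    H = _graph_from_int_edges(G, edges)
    return H, PerturbationSpec(f=f, seed=seed, M_before=G.M, M_after=H.M)
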