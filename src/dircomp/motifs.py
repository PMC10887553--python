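"""Directed-motif catalogue and per-node motif census.

A *motif class* is an isomorphism class of weakly connected digraphs on 2-4
nodes, identified by a canonical code: the lexicographically minimal row-major
bit-string of the adjacency matrix over all node permutations.  The default
catalogue has 35 classes — the complete enumerations of sizes 2 (2 classes)
and 3 (13 classes, the connected triad census) plus a packaged list of 20
four-node classes (see ``data/motif_catalogue.tsv``).  The census code is
generic over any catalogue, including the complete 199-class four-node
enumeration.

Motif *instances* are induced, weakly connected subgraphs, enumerated exactly
once each by an ESU-style search on the symmetrized adjacency.  The census
records, for every node, how many instances of each class contain it; row
normalization of those counts gives the per-node motif distribution matrix T
used by the dissimilarity measure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .graph import DirectedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "MotifClass",
    "MotifCatalogue",
    "NodeMotifMatrix",
    "canonical_code",
    "enumerate_motif_classes",
    "build_catalogue",
    "enumerate_connected_induced_subgraphs",
    "motif_participation_counts",
    "node_motif_distribution",
]


# ---------------------------------------------------------------------------
# canonical labeling of small digraphs
# ---------------------------------------------------------------------------

def canonical_code(adjacency) -> str:
    """Canonical code of a small digraph adjacency matrix.

    Minimum over all node permutations of the row-major 0/1 string of the
    permuted matrix; isomorphic digraphs share the code, non-isomorphic ones
    differ (guaranteed by exhausting all k! permutations).

    Only sizes 2-4 are supported; the diagonal must be zero.
    """
    A = np.asarray(adjacency, dtype=int)
    k = A.shape[0]
    if A.shape != (k, k) or k < 2 or k > 4:
        raise ValueError("adjacency must be square with 2 <= k <= 4 nodes")
    if np.any(np.diag(A)):
        raise ValueError("self-loops are not allowed in motif classes")
    rows = [tuple(int(x) for x in row) for row in A]
    best = None
    for perm in itertools.permutations(range(k)):
        bits = "".join("1" if rows[i][j] else "0" for i in perm for j in perm)
        if best is None or bits < best:
            best = bits
    return best  # type: ignore[return-value]


def _offdiag_pairs(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(k) if i != j]


def _matrix_from_packed(code: int, k: int) -> np.ndarray:
    A = np.zeros((k, k), dtype=int)
    for b, (i, j) in enumerate(_offdiag_pairs(k)):
        if (code >> b) & 1:
            A[i, j] = 1
    return A


def _is_weakly_connected(A: np.ndarray) -> bool:
    k = len(A)
    U = (A + A.T) > 0
    reach = np.zeros(k, dtype=bool)
    reach[0] = True
    for _ in range(k):  # fixed-point expansion; k steps always suffice
        reach = reach | U[reach].any(axis=0)
    return bool(reach.all())


def enumerate_motif_classes(k: int) -> list[str]:
    """All weakly connected digraph classes on ``k`` nodes (canonical codes),
    sorted by edge count then code.  Sizes 2, 3, 4 give 2, 13, 199 classes."""
    if k < 2 or k > 4:
        raise ValueError("motif sizes 2-4 only")
    seen: dict[str, int] = {}
    for code in range(1 << (k * (k - 1))):
        A = _matrix_from_packed(code, k)
        if not _is_weakly_connected(A):
            continue
        c = canonical_code(A)
        if c not in seen:
            seen[c] = int(A.sum())
    return sorted(seen, key=lambda c: (seen[c], c))


# ---------------------------------------------------------------------------
# catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifClass:
    """One motif isomorphism class."""

    id: str
    size: int
    canonical_code: str

    @property
    def adjacency(self) -> np.ndarray:
        k = self.size
        return np.array([int(b) for b in self.canonical_code], dtype=int).reshape(k, k)

    @property
    def n_edges(self) -> int:
        return self.canonical_code.count("1")


class CatalogueIntegrityError(ValueError):
    """Packaged or user catalogue violates a structural requirement."""


@dataclass
class MotifCatalogue:
    """Ordered list of motif classes with fast classification tables."""

    classes: list[MotifClass]
    _col_of_code: dict[str, int] = field(init=False, repr=False)
    _lookup: dict[int, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        codes = [c.canonical_code for c in self.classes]
        if len(set(codes)) != len(codes):
            raise CatalogueIntegrityError("duplicate motif classes in catalogue")
        for c in self.classes:
            A = c.adjacency
            if canonical_code(A) != c.canonical_code:
                raise CatalogueIntegrityError(
                    f"class {c.id}: code is not canonical"
                )
            if not _is_weakly_connected(A):
                raise CatalogueIntegrityError(f"class {c.id}: not weakly connected")
        self._col_of_code = {c.canonical_code: j for j, c in enumerate(self.classes)}
        self._lookup = {}
        for k in sorted({c.size for c in self.classes}):
            self._lookup[k] = self._build_lookup(k)

    def _build_lookup(self, k: int) -> list[int]:
        """Map every packed off-diagonal adjacency code (any labeling) to its
        catalogue column, -1 for connected-but-uncatalogued, -2 for
        disconnected."""
        table = [-2] * (1 << (k * (k - 1)))
        for code in range(len(table)):
            A = _matrix_from_packed(code, k)
            if not _is_weakly_connected(A):
                continue
            table[code] = self._col_of_code.get(canonical_code(A), -1)
        return table

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self) -> Iterator[MotifClass]:
        return iter(self.classes)

    def __getitem__(self, j: int) -> MotifClass:
        return self.classes[j]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.classes]

    @property
    def sizes(self) -> list[int]:
        return sorted({c.size for c in self.classes})

    def size_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.classes:
            out[c.size] = out.get(c.size, 0) + 1
        return out

    def column_of(self, adjacency) -> int:
        """Catalogue column of an adjacency matrix, or -1 if not present."""
        return self._col_of_code.get(canonical_code(adjacency), -1)


def _packaged_classes() -> list[tuple[str, int, str]]:
    text = (
        resources.files("dircomp").joinpath("data/motif_catalogue.tsv").read_text()
    )
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mid, size, code = line.split("\t")
        rows.append((mid, int(size), code))
    return rows


def build_catalogue(
    sizes: Iterable[int] = (2, 3, 4),
    four_node: str = "default",
) -> MotifCatalogue:
    """Build the motif catalogue.

    Sizes 2 and 3 are always the complete enumerations of weakly connected
    digraph classes.  For size 4, ``four_node='default'`` uses the packaged
    20-class list (total 35 classes with all sizes), while
    ``four_node='complete'`` enumerates all 199 connected four-node classes.
    Ids are assigned ``m1, m2, ...`` in catalogue order.
    """
    sizes = sorted(set(sizes))
    if not sizes or any(k not in (2, 3, 4) for k in sizes):
        raise ValueError("sizes must be a non-empty subset of {2, 3, 4}")
    packaged = _packaged_classes()
    classes: list[MotifClass] = []
    for k in sizes:
        if k == 4 and four_node == "default":
            codes = [code for _, size, code in packaged if size == 4]
        elif k == 4 and four_node == "complete":
            codes = enumerate_motif_classes(4)
        elif k == 4:
            raise ValueError("four_node must be 'default' or 'complete'")
        else:
            codes = enumerate_motif_classes(k)
        classes.extend(
            MotifClass(id="", size=k, canonical_code=code) for code in codes
        )
    classes = [
        MotifClass(id=f"m{j + 1}", size=c.size, canonical_code=c.canonical_code)
        for j, c in enumerate(classes)
    ]
    return MotifCatalogue(classes=classes)


# ---------------------------------------------------------------------------
# subgraph enumeration (ESU on the weakly symmetrized adjacency)
# ---------------------------------------------------------------------------

def enumerate_connected_induced_subgraphs(
    G: DirectedGraph, k: int
) -> Iterator[tuple[str, ...]]:
    """Yield every k-node subset inducing a weakly connected subgraph, once.

    ``k > N`` yields nothing.  Order of subsets is unspecified; within a
    subset, labels follow the graph's node order.
    """
    if k < 2 or k > 4:
        raise ValueError("subgraph sizes 2-4 only")
    labels = G.nodes
    _, und = G.bitmask_adjacency()
    for subset in _esu_subsets(und, G.N, k):
        yield tuple(labels[i] for i in subset)


def _esu_subsets(und: Sequence[int], n: int, k: int) -> Iterator[tuple[int, ...]]:
    """ESU enumeration of connected k-subsets over bitmask adjacency."""
    if k == 1:
        for v in range(n):
            yield (v,)
        return

    def extend(sub: tuple[int, ...], ext: int, closed: int, gt: int):
        if len(sub) == k - 1:
            while ext:
                wbit = ext & -ext
                ext ^= wbit
                yield sub + (wbit.bit_length() - 1,)
            return
        while ext:
            wbit = ext & -ext
            ext ^= wbit
            w = wbit.bit_length() - 1
            new_ext = ext | (und[w] & ~closed & gt)
            yield from extend(sub + (w,), new_ext, closed | und[w] | wbit, gt)

    for v in range(n):
        gt = -1 << (v + 1)
        ext = und[v] & gt
        closed = und[v] | (1 << v)
        yield from extend((v,), ext, closed, gt)


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

@dataclass
class NodeMotifMatrix:
    """Per-node motif participation, in counts and distribution form.

    ``counts[i, j]`` is the number of induced, weakly connected subgraph
    instances of catalogue class ``j`` that contain node ``i``.
    ``unclassified[i]`` tallies enumerated instances whose class is not in
    the catalogue (possible only with the default 20-class four-node list).
    """

    nodes: tuple[str, ...]
    catalogue: MotifCatalogue
    counts: np.ndarray
    unclassified: np.ndarray

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.nodes), columns=self.catalogue.ids)

    def distribution(self) -> np.ndarray:
        """Row-normalized motif distribution matrix T (zero rows preserved)."""
        return node_motif_distribution(self.counts)

    def distribution_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.distribution(), index=list(self.nodes), columns=self.catalogue.ids
        )


def node_motif_distribution(counts: np.ndarray) -> np.ndarray:
    """Normalize each row of a non-negative count matrix to sum 1.

    Rows that are entirely zero (motif-less nodes) stay zero.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    sums = counts.sum(axis=1, keepdims=True)
    T = np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)
    return T


def motif_participation_counts(
    G: DirectedGraph, catalogue: MotifCatalogue | None = None
) -> NodeMotifMatrix:
    """Census of per-node participation in every catalogue motif class.

    Enumerates all induced weakly connected subgraphs of the catalogue's
    sizes with an ESU search and classifies each through a precomputed
    code-to-column table; instances outside the catalogue go to the
    per-node ``unclassified`` tally.
    """
    if catalogue is None:
        catalogue = build_catalogue()
    n = G.N
    ncols = len(catalogue)
    counts = [0] * (n * ncols)
    unclassified = [0] * n
    out, und = G.bitmask_adjacency()
    for k in catalogue.sizes:
        lookup = catalogue._lookup[k]
        pairs = _offdiag_pairs(k)
        for subset in _esu_subsets(und, n, k):
            code = 0
            for b, (pi, pj) in enumerate(pairs):
                if (out[subset[pi]] >> subset[pj]) & 1:
                    code |= 1 << b
            col = lookup[code]
            if col >= 0:
                base = col
                for node in subset:
                    counts[node * ncols + base] += 1
            else:
                for node in subset:
                    unclassified[node] += 1
    unc = np.asarray(unclassified, dtype=np.int64)
    if unc.sum():
        logger.info(
            "census: %d subgraph instance participations outside the catalogue",
            int(unc.sum()),
        )
    return NodeMotifMatrix(
        nodes=G.nodes,
        catalogue=catalogue,
        counts=np.asarray(counts, dtype=np.int64).reshape(n, ncols),
        unclassified=unc,
    )
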