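import numpy as np
import pytest

from dircomp import build_catalogue, generate_er_digraph, toy_fixtures


@pytest.fixture(scope="session")
def catalogue():
    return build_catalogue()


@pytest.fixture(scope="session")
def full_catalogue():
    """All 2-, 3- and 4-node classes (2 + 13 + 199)."""
    return build_catalogue(four_node="complete")


@pytest.fixture(scope="session")
def toys():
    return toy_fixtures()


@pytest.fixture
def er_factory():
    def make(n=30, p=0.1, seed=0):
        return generate_er_digraph(n, p=p, seed=seed)

    return make


def brute_force_connected_subsets(G, k):
    """Oracle: test all C(N, k) subsets for weak connectivity of the induced
    subgraph.  Independent of the ESU enumerator."""
    import itertools

    nodes = list(G.nodes)
    out = []
    for subset in itertools.combinations(nodes, k):
        members = set(subset)
        induced = [(u, v) for u, v in G.edges if u in members and v in members]
        if not induced:
            continue
        # weak connectivity by union-find over undirected versions
        parent = {u: u for u in subset}

        def find(u):
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        for u, v in induced:
            parent[find(u)] = find(v)
        if len({find(u) for u in subset}) == 1:
            out.append(tuple(sorted(subset)))
    return sorted(out)


def brute_force_counts(G, catalogue):
    """Oracle census: classify every connected subset's induced adjacency
    through the public canonical-code routine."""
    import numpy as _np

    from dircomp import canonical_code

    code_col = {c.canonical_code: j for j, c in enumerate(catalogue.classes)}
    counts = _np.zeros((G.N, len(catalogue)), dtype=int)
    node_row = {u: i for i, u in enumerate(G.nodes)}
    for k in catalogue.sizes:
        for subset in brute_force_connected_subsets(G, k):
            A = _np.zeros((k, k), dtype=int)
            pos = {u: i for i, u in enumerate(subset)}
            for u, v in G.edges:
                if u in pos and v in pos:
                    A[pos[u], pos[v]] = 1
            col = code_col.get(canonical_code(A))
            if col is None:
                continue
            for u in subset:
                counts[node_row[u], col] += 1
    return counts
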