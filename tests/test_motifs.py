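"""Motif catalogue, canonical labeling and the per-node census."""

import numpy as np
import pytest

from dircomp import (
    DirectedGraph,
    build_catalogue,
    canonical_code,
    directed_cycle,
    directed_path,
    enumerate_connected_induced_subgraphs,
    generate_er_digraph,
    motif_participation_counts,
    node_motif_distribution,
    out_star,
)
from dircomp.motifs import CatalogueIntegrityError, MotifClass, MotifCatalogue, enumerate_motif_classes

from conftest import brute_force_connected_subsets, brute_force_counts


class TestCanonicalCode:
    def test_isomorphic_labelings_share_code(self):
        a = [[0, 1], [0, 0]]
        b = [[0, 0], [1, 0]]
        assert canonical_code(a) == canonical_code(b)

    def test_three_cycle_all_labelings_one_code(self):
        import itertools

        base = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        codes = set()
        for perm in itertools.permutations(range(3)):
            P = np.eye(3, dtype=int)[list(perm)]
            codes.add(canonical_code(P @ base @ P.T))
        assert len(codes) == 1

    def test_in_star_vs_out_star_distinct(self):
        # a->b<-c vs a<-b->c are non-isomorphic: brute-force check
        in_star_m = np.array([[0, 1, 0], [0, 0, 0], [0, 1, 0]])
        out_star_m = np.array([[0, 0, 0], [1, 0, 1], [0, 0, 0]])
        assert canonical_code(in_star_m) != canonical_code(out_star_m)

    @pytest.mark.parametrize("k", [1, 5])
    def test_size_out_of_range(self, k):
        with pytest.raises(ValueError):
            canonical_code(np.zeros((k, k), dtype=int))

    def test_diagonal_must_be_zero(self):
        with pytest.raises(ValueError, match="self-loop"):
            canonical_code(np.eye(2, dtype=int))


class TestCatalogue:
    @pytest.mark.parametrize("k,count", [(2, 2), (3, 13), (4, 199)])
    def test_complete_class_counts(self, k, count):
        assert len(enumerate_motif_classes(k)) == count

    def test_default_catalogue_has_35_classes(self, catalogue):
        assert len(catalogue) == 35
        assert catalogue.size_counts() == {2: 2, 3: 13, 4: 20}
        assert catalogue.ids[0] == "m1" and catalogue.ids[-1] == "m35"

    def test_size_subsets(self):
        assert len(build_catalogue(sizes={2})) == 2
        assert len(build_catalogue(sizes={3})) == 13
        assert len(build_catalogue(sizes={2, 3})) == 15

    def test_first_two_classes_are_edge_and_mutual_dyad(self, catalogue):
        assert catalogue[0].size == 2 and catalogue[0].n_edges == 1
        assert catalogue[1].size == 2 and catalogue[1].n_edges == 2

    def test_codes_pairwise_distinct_and_canonical(self, full_catalogue):
        codes = [c.canonical_code for c in full_catalogue]
        assert len(set(codes)) == len(codes) == 2 + 13 + 199
        for c in full_catalogue:
            assert canonical_code(c.adjacency) == c.canonical_code

    def test_duplicate_classes_rejected(self):
        cls = MotifClass(id="m1", size=2, canonical_code="0010")
        with pytest.raises(CatalogueIntegrityError):
            MotifCatalogue(classes=[cls, cls])

    def test_disconnected_class_rejected(self):
        bad = MotifClass(id="m1", size=3, canonical_code="0" * 9)
        with pytest.raises(CatalogueIntegrityError):
            MotifCatalogue(classes=[bad])


class TestEnumeration:
    def test_cycle_subsets(self):
        g = directed_cycle(3)
        assert len(list(enumerate_connected_induced_subgraphs(g, 2))) == 3
        assert len(list(enumerate_connected_induced_subgraphs(g, 3))) == 1

    def test_path_excludes_disconnected_pair(self):
        g = directed_path(3)
        pairs = list(enumerate_connected_induced_subgraphs(g, 2))
        assert len(pairs) == 2

    def test_star_counts(self):
        g = out_star(4)
        assert len(list(enumerate_connected_induced_subgraphs(g, 3))) == 3
        assert len(list(enumerate_connected_induced_subgraphs(g, 4))) == 1

    def test_k_larger_than_n_yields_nothing(self):
        g = directed_path(3)
        assert list(enumerate_connected_induced_subgraphs(g, 4)) == []

    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(10):
            g = generate_er_digraph(9, p=0.2, seed=seed)
            for k in (2, 3, 4):
                fast = sorted(
                    tuple(sorted(s))
                    for s in enumerate_connected_induced_subgraphs(g, k)
                )
                assert fast == brute_force_connected_subsets(g, k)


class TestCensus:
    def test_single_edge(self, catalogue):
        g = DirectedGraph(edges=[("a", "b")])
        result = motif_participation_counts(g, catalogue)
        frame = result.counts_frame()
        assert (frame["m1"] == 1).all()
        assert frame.drop(columns="m1").to_numpy().sum() == 0

    def test_mutual_dyad_is_m2(self, catalogue):
        g = DirectedGraph(edges=[("a", "b"), ("b", "a")])
        frame = motif_participation_counts(g, catalogue).counts_frame()
        assert (frame["m2"] == 1).all()
        assert frame.drop(columns="m2").to_numpy().sum() == 0

    def test_three_cycle_counts_and_distribution(self, catalogue):
        g = directed_cycle(3)
        result = motif_participation_counts(g, catalogue)
        row = result.counts_frame().loc["n0"]
        assert row["m1"] == 2  # two single-edge instances contain each node
        cycle_cols = row[row > 0].index.tolist()
        assert len(cycle_cols) == 2  # m1 and the 3-cycle class
        T = result.distribution_frame().loc["n0"]
        assert T[cycle_cols].tolist() == pytest.approx([2 / 3, 1 / 3])

    def test_column_totals_are_size_times_instances(self, full_catalogue):
        g = generate_er_digraph(10, p=0.25, seed=5)
        result = motif_participation_counts(g, full_catalogue)
        totals = result.counts.sum(axis=0)
        for j, cls in enumerate(full_catalogue):
            assert totals[j] % cls.size == 0
        # complete catalogue: every instance classified
        assert result.unclassified.sum() == 0
        n_instances = sum(
            len(list(enumerate_connected_induced_subgraphs(g, k))) for k in (2, 3, 4)
        )
        assert int((totals / [c.size for c in full_catalogue]).sum()) == n_instances

    def test_census_equals_brute_force_oracle(self, full_catalogue):
        for seed in range(5):
            g = generate_er_digraph(8, p=0.3, seed=seed)
            fast = motif_participation_counts(g, full_catalogue).counts
            assert np.array_equal(fast, brute_force_counts(g, full_catalogue))

    def test_default_catalogue_diagnostic_tally(self, catalogue):
        # dense 4-node digraphs fall outside the 20-class default list
        g = generate_er_digraph(8, p=0.7, seed=1)
        result = motif_participation_counts(g, catalogue)
        assert result.unclassified.sum() > 0

    def test_permutation_invariance(self, catalogue):
        g = generate_er_digraph(10, p=0.2, seed=9)
        mapping = {u: f"z{i}" for i, u in enumerate(reversed(g.nodes))}
        h = g.relabel(mapping)
        Tg = motif_participation_counts(g, catalogue).distribution_frame()
        Th = motif_participation_counts(h, catalogue).distribution_frame()
        rows_g = sorted(map(tuple, Tg.round(12).to_numpy().tolist()))
        rows_h = sorted(map(tuple, Th.round(12).to_numpy().tolist()))
        assert rows_g == rows_h


class TestDistribution:
    def test_rows_sum_to_one_or_zero(self, catalogue):
        g = generate_er_digraph(20, p=0.05, seed=2)
        T = motif_participation_counts(g, catalogue).distribution()
        sums = T.sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))

    def test_isolated_node_row_is_zero(self, catalogue):
        g = DirectedGraph(nodes=["iso"], edges=[("a", "b")])
        T = motif_participation_counts(g, catalogue).distribution_frame()
        assert (T.loc["iso"] == 0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            node_motif_distribution(np.array([[-1.0, 2.0]]))
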