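"""Fisher exact homology testing, fate calling and FWM co-occurrence."""

import math

import numpy as np
import pytest

from conftest import make_table
from karyofuse.homology import (
    HomologyGraph,
    HomologyMatrix,
    bonferroni,
    chromosome_fate,
    classify_fused_pair,
    cooccurrence_fwm_test,
    count_fused,
    fisher_association,
    fused_reference_pairs,
    shared_ortholog_matrix,
    significant_homologies,
    score_homologies,
)
from karyofuse.karyosim import emit_observed, evolve, make_ancestor, random_fusion_scenario
from karyofuse.pipeline import analyze_homology


def brute_force_tail(a: int, n_total: int, row: int, col: int) -> float:
    """P(X >= a) by exact integer enumeration of the hypergeometric pmf."""
    lo, hi = max(0, row + col - n_total), min(row, col)
    total = math.comb(n_total, col)
    tail = sum(
        math.comb(row, x) * math.comb(n_total - row, col - x)
        for x in range(max(a, lo), hi + 1)
    )
    return tail / total


class TestSharedMatrix:
    def test_two_block_counts(self, two_block_table):
        m = shared_ortholog_matrix(two_block_table)
        assert m.counts.tolist() == [[10, 0], [0, 10]]
        assert m.n_total == 20

    def test_single_ortholog(self):
        m = shared_ortholog_matrix(make_table([("A", "B")]))
        assert m.counts.tolist() == [[1]]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            shared_ortholog_matrix(make_table([("A", "B")][:0]))


class TestFisher:
    def test_diagonal_block_closed_form(self, two_block_table):
        m = shared_ortholog_matrix(two_block_table)
        assert fisher_association(m, 0, 0) == pytest.approx(
            1 / math.comb(20, 10), rel=1e-12
        )

    def test_balanced_table(self):
        m = HomologyMatrix(["A1", "A2"], ["B1", "B2"], [[5, 5], [5, 5]])
        assert fisher_association(m, 0, 0) == pytest.approx(
            brute_force_tail(5, 20, 10, 10), abs=1e-14
        )

    def test_zero_cell_has_p_one(self):
        m = HomologyMatrix(["A1", "A2"], ["B1", "B2"], [[0, 10], [10, 0]])
        assert fisher_association(m, 0, 0) == pytest.approx(1.0)

    def test_agrees_with_enumeration_on_random_margins(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 41))
            row = int(rng.integers(1, n + 1))
            col = int(rng.integers(1, n + 1))
            a = int(rng.integers(max(0, row + col - n), min(row, col) + 1))
            b, c = row - a, col - a
            m = HomologyMatrix(
                ["A1", "A2"], ["B1", "B2"],
                [[a, b], [c, n - a - b - c]],
            )
            assert fisher_association(m, 0, 0) == pytest.approx(
                brute_force_tail(a, n, row, col), abs=1e-12
            )


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni(np.array([0.001]), 46)[0] == pytest.approx(0.046)
        assert bonferroni(np.array([0.5]), 10)[0] == 1.0
        assert bonferroni(np.array([0.3]), 1)[0] == pytest.approx(0.3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([1.2]), 2)


class TestAssociationGraph:
    def test_two_block_gives_two_edges(self, two_block_table):
        m = score_homologies(shared_ortholog_matrix(two_block_table))
        graph = significant_homologies(m, alpha=0.05)
        assert graph.edges == {("A1", "B1"), ("A2", "B2")}

    def test_alpha_zero_gives_no_edges(self, two_block_table):
        m = score_homologies(shared_ortholog_matrix(two_block_table))
        assert significant_homologies(m, alpha=0.0).n_edges == 0


def graph_from_edges(edges, refs, queries):
    g = HomologyGraph({a: set() for a in refs}, {b: set() for b in queries})
    for a, b in edges:
        g.a_partners[a].add(b)
        g.b_partners[b].add(a)
    return g


class TestFates:
    def test_one_to_one(self):
        g = graph_from_edges([("A", "S")], ["A"], ["S"])
        assert chromosome_fate(g, "A").fate == "one_to_one"

    def test_fusion_partner_shared(self):
        g = graph_from_edges([("A", "S"), ("B", "S")], ["A", "B"], ["S"])
        assert chromosome_fate(g, "A").fate == "fused"
        assert chromosome_fate(g, "B").fate == "fused"
        assert fused_reference_pairs(g) == {frozenset(("A", "B"))}

    def test_fission_gives_split(self):
        g = graph_from_edges([("A", "S1"), ("A", "S2")], ["A"], ["S1", "S2"])
        assert chromosome_fate(g, "A").fate == "split"

    def test_degree_zero_is_unplaced(self):
        g = graph_from_edges([], ["A"], ["S"])
        assert chromosome_fate(g, "A").fate == "unplaced"

    def test_unknown_reference_rejected(self):
        g = graph_from_edges([], ["A"], ["S"])
        with pytest.raises(KeyError):
            chromosome_fate(g, "Z")

    def test_fates_invariant_under_relabeling(self):
        anc = make_ancestor(8, 30)
        events = random_fusion_scenario(anc, n_fuse_mix=2, seed=5)
        desc, _ = evolve(anc, events, seed=5)
        table = emit_observed(anc, desc, retention=1.0, seed=5)
        base = analyze_homology(table, min_genes=1)
        fates = {f.scaffold: f.fate for f in base.fates}

        relabel = {s: f"X{i}" for i, s in enumerate(sorted(table.df["scaffold_a"].unique()))}
        df = table.df.copy()
        df["scaffold_a"] = df["scaffold_a"].map(relabel)
        from karyofuse.io_formats import SyntenyTable

        relabeled = analyze_homology(SyntenyTable(df), min_genes=1)
        fates2 = {f.scaffold: f.fate for f in relabeled.fates}
        assert fates2 == {relabel[s]: f for s, f in fates.items()}


class TestCooccurrence:
    def test_perfect_cooccurrence(self):
        # 10 contigs carry both refs, 10 carry neither
        rows = []
        for i in range(10):
            rows += [("R1", f"c{i:02d}"), ("R2", f"c{i:02d}")]
        for i in range(10, 20):
            rows.append(("R3", f"c{i:02d}"))
        table = make_table(rows)
        p = cooccurrence_fwm_test(table, "R1", "R2", ref_side="a")
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_segregated_refs_not_significant(self):
        rows = [("R1", f"c{i}") for i in range(10)] + [
            ("R2", f"d{i}") for i in range(10)
        ]
        table = make_table(rows)
        assert cooccurrence_fwm_test(table, "R1", "R2") == pytest.approx(1.0)

    def test_absent_ref_rejected(self, two_block_table):
        with pytest.raises(KeyError):
            cooccurrence_fwm_test(two_block_table, "A1", "missing")


class TestCountFused:
    def test_no_events_means_no_fusions(self):
        anc = make_ancestor(6, 30)
        table = emit_observed(anc, anc, retention=1.0, seed=0)
        analysis = analyze_homology(table, min_genes=1)
        assert analysis.count_fused() == (0, 6, 6)

    def test_two_fusions_mark_four_chromosomes(self):
        anc = make_ancestor(6, 30)
        events = random_fusion_scenario(anc, n_fuse_mix=2, seed=2)
        desc, _ = evolve(anc, events, seed=2)
        table = emit_observed(anc, desc, retention=1.0, seed=2)
        analysis = analyze_homology(table, min_genes=1)
        assert analysis.count_fused() == (4, 2, 6)
        assert analysis.fused_pairs == {frozenset(e.participants) for e in events}

    def test_contig_mode_on_fragmented_fusion(self):
        from karyofuse.karyosim import FragmentationProfile, fragment_genome

        anc = make_ancestor(6, 60)
        events = random_fusion_scenario(anc, n_fuse_mix=1, seed=4)
        desc, _ = evolve(anc, events, seed=4)
        frag = fragment_genome(desc, FragmentationProfile((20,)), seed=4)
        table = emit_observed(anc, frag, retention=1.0, seed=4)
        n_fused, n_unfused, total = count_fused(table, mode="contig")
        assert (n_fused, total) == (2, 6)


class TestClassifyFusedPair:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.081, "sharp"), (0.193, "mixed"), (0.105, "mixed")],
    )
    def test_against_quartile_range(self, value, expected):
        assert classify_fused_pair(value, (0.105, 0.209)) == expected

    def test_inverted_quartiles_rejected(self):
        with pytest.raises(ValueError):
            classify_fused_pair(0.1, (0.3, 0.2))
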