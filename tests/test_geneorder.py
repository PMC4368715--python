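"""Signed gene orders: equality, breakpoints, blocks, displaced genes."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoprofile import (
    SignedGeneOrder,
    breakpoint_distance,
    compare_orders,
    conserved_blocks,
    displaced_genes,
    ground_plan_order,
    to_signed_order,
)
from mitoprofile.annotation import rotate_annotation
from mitoprofile.synthetic import perturb_order

from .conftest import breakpoint_oracle


def order_of(text: str) -> SignedGeneOrder:
    return SignedGeneOrder.from_string(text)


@st.composite
def signed_orders(draw, min_size=3, max_size=9):
    n = draw(st.integers(min_size, max_size))
    labels = [f"g{i}" for i in range(n)]
    perm = draw(st.permutations(labels))
    signs = draw(st.lists(st.sampled_from([1, -1]), min_size=n, max_size=n))
    return SignedGeneOrder(tuple(zip(perm, signs)))


class TestStructure:
    def test_bundled_annotation_gives_31_gene_order(self, gene_table):
        order = to_signed_order(gene_table)
        assert len(order) == 31
        anchored = order.anchored("cox1")
        assert anchored.genes[:4] == (
            ("cox1", 1),
            ("cox2", 1),
            ("cox3", 1),
            ("trnG", 1),  # nested tRNA linearised by start coordinate
        )

    def test_single_gene_annotation(self):
        from .conftest import toy_annotation

        order = to_signed_order(toy_annotation(10, [("g", "-", 2, 7)]))
        assert order.genes == (("g", -1),)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            order_of("a b a")

    def test_string_round_trip(self):
        text = "cox1 -trnF nad5 -rrnS"
        assert order_of(text).to_string() == text

    def test_rotated_annotation_gives_equivalent_order(self, gene_table):
        rotated = rotate_annotation(gene_table, 40)
        assert to_signed_order(gene_table).equivalent(to_signed_order(rotated))

    def test_equality_up_to_rotation_and_reversal(self):
        o = order_of("a b -c d")
        assert o.equivalent(o.rotate(2))
        assert o.equivalent(o.reverse())
        assert not o.equivalent(order_of("a b c d"))


class TestBreakpoints:
    def test_identical_orders(self):
        o = order_of("a b c d e")
        assert breakpoint_distance(o, o) == 0

    def test_transposed_pair_costs_three(self):
        o1 = order_of("a b c d e")
        o2 = order_of("a b d c e")
        assert breakpoint_distance(o1, o2) == 3

    def test_inverted_gene_costs_two(self):
        o1 = order_of("a b c d e")
        o2 = order_of("a -b c d e")
        assert breakpoint_distance(o1, o2) == 2

    def test_strigamia_vs_ground_plan_matches_oracle(self, gene_table):
        o1 = to_signed_order(gene_table)
        o2 = ground_plan_order()
        assert breakpoint_distance(o1, o2) == breakpoint_oracle(o1, o2)

    def test_exhaustive_small_orders_match_oracle(self):
        """Every signed circular order on 5 labels vs a fixed reference."""
        ref = order_of("a b c d e")
        labels = ["a", "b", "c", "d", "e"]
        for perm in itertools.permutations(labels[1:]):
            for signs in itertools.product([1, -1], repeat=5):
                o = SignedGeneOrder(
                    tuple(zip(["a", *perm], signs))
                )
                assert breakpoint_distance(o, ref) == breakpoint_oracle(
                    o, ref
                )

    @given(o1=signed_orders(), o2=signed_orders())
    @settings(max_examples=150, deadline=None)
    def test_random_orders_match_oracle_and_invariants(self, o1, o2):
        d = breakpoint_distance(o1, o2)
        assert d == breakpoint_oracle(o1, o2)
        assert d == breakpoint_distance(o2, o1)  # symmetry
        assert breakpoint_distance(o1.rotate(1), o2) == d
        assert breakpoint_distance(o1.reverse(), o2) == d
        comparison = compare_orders(o1, o2)
        assert comparison.shared_adjacencies + comparison.breakpoints == len(
            comparison.common_labels
        )

    def test_common_set_too_small_rejected(self):
        with pytest.raises(ValueError):
            breakpoint_distance(order_of("a b c"), order_of("a x y"))


class TestBlocks:
    def test_identical_orders_form_one_block(self):
        o = order_of("a b -c d e")
        (block,) = conserved_blocks(o, o)
        assert len(block) == 5

    def test_reversed_order_forms_one_block(self):
        o = order_of("a b -c d e")
        (block,) = conserved_blocks(o, o.reverse())
        assert len(block) == 5

    def test_strict_blocks_vs_ground_plan(self, gene_table):
        blocks = conserved_blocks(to_signed_order(gene_table),
                                  ground_plan_order())
        sets = {b.labels for b in blocks}
        assert ("cox1", "cox2") in sets
        assert ("trnD", "atp8", "atp6") in sets
        assert ("trnF", "nad5", "trnH", "nad4", "nad4l") in sets

    def test_gap_tolerant_blocks_recover_figure_level_runs(self, gene_table):
        """Allowing one intervening translocated gene recovers the full
        minus-strand run including trnP and the nad1-rrnL-rrnS run."""
        blocks = conserved_blocks(
            to_signed_order(gene_table), ground_plan_order(), max_gap=1
        )
        sets = {b.labels for b in blocks}
        assert ("trnF", "nad5", "trnH", "nad4", "nad4l", "trnP") in sets
        assert ("nad1", "rrnL", "rrnS") in sets

    def test_breakpoint_free_pairs_are_covered_by_blocks(self):
        o1 = order_of("a b c d e f")
        o2 = order_of("a b c f -e -d")
        blocks = conserved_blocks(o1, o2)
        covered = {g for b in blocks for g in b.labels}
        assert {"a", "b", "c"} <= covered
        assert {"d", "e"} <= covered  # conserved as a reversed run


class TestDisplaced:
    def test_identical_orders_have_none(self):
        o = order_of("a b c d e f")
        assert displaced_genes(o, o) == []

    def test_single_moved_gene_detected_with_context(self):
        o1 = order_of("a b c d e f")
        o2 = order_of("a c d e b f")  # b moved between e and f
        out = displaced_genes(o1, o2)
        assert [g for g, _ in out] == ["b"]
        ctx = out[0][1]
        assert ctx["first_order_context"] == ("a", "c")
        assert ctx["second_order_context"] == ("e", "f")

    def test_strigamia_vs_ground_plan_is_consistent_with_blocks(
        self, gene_table
    ):
        o1 = to_signed_order(gene_table)
        o2 = ground_plan_order()
        displaced = {g for g, _ in displaced_genes(o1, o2)}
        in_blocks = {
            g for b in conserved_blocks(o1, o2) for g in b.labels
        }
        assert displaced.isdisjoint(in_blocks)
        assert displaced | in_blocks == o1.labels & o2.labels


class TestPerturbation:
    def test_translocation_between_conserved_neighbours_costs_three(self):
        o1 = order_of("a b c d e f")
        o2 = order_of("a c d b e f")  # b translocated between d and e
        assert breakpoint_distance(o1, o2) == 3

    @given(
        seed=st.integers(0, 2**31 - 1),
        k=st.integers(0, 4),
    )
    @settings(max_examples=60, deadline=None)
    def test_k_moves_break_at_most_3k_adjacencies(self, seed, k):
        o = order_of("a b c d e f g h")
        moved, _ = perturb_order(o, n_translocations=k, n_inversions=0,
                                 seed=seed)
        assert breakpoint_distance(o, moved) <= 3 * k
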