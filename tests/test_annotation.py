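"""Parsing, coordinate arithmetic and validation of circular annotations."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoprofile import (
    GeneFeature,
    feature_length,
    intergenic_value,
    parse_annotation,
    validate_annotation,
    write_annotation,
)
from mitoprofile.annotation import rotate_annotation
from mitoprofile.errors import (
    AnnotationParseError,
    CoordinateError,
    RangeError,
)

from .conftest import GENOME_LENGTH, toy_annotation


class TestParsing:
    def test_bundled_table_feature_counts(self, gene_table):
        """The published table yields 33 features: 13 PCG, 2 rRNA, 16 tRNA, 2 NC."""
        assert len(gene_table) == 33
        assert len(gene_table.by_category("PCG")) == 13
        assert len(gene_table.by_category("rRNA")) == 2
        assert len(gene_table.by_category("tRNA")) == 16
        assert len(gene_table.by_category("NC")) == 2

    def test_single_row_whole_circle(self):
        ann = parse_annotation("gene,strand,start,end\ng,+,1,9\n", 9)
        (f,) = ann.features
        assert (f.category, f.start, f.end) == ("PCG", 1, 9)

    def test_start_after_end_rejected(self):
        with pytest.raises(CoordinateError):
            parse_annotation("gene\tstrand\tstart\tend\ng\t+\t10\t5\n", 20)

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            parse_annotation("gene\tstrand\tstart\tend\ng\t+\t1\t30\n", 20)

    @pytest.mark.parametrize(
        "text",
        [
            "gene\tstrand\tstart\tend\ng\t+\t1\n",  # short row
            "gene\tstrand\tstart\tend\ng\t+\tx\t5\n",  # non-numeric
            "gene\tstart\tend\ng\t1\t5\n",  # missing strand column
        ],
    )
    def test_malformed_rows_name_the_line(self, text):
        with pytest.raises(AnnotationParseError) as err:
            parse_annotation(text, 20)
        assert "line" in str(err.value)

    def test_duplicate_names_rejected(self):
        text = "gene\tstrand\tstart\tend\ng\t+\t1\t5\ng\t+\t6\t9\n"
        with pytest.raises(AnnotationParseError):
            parse_annotation(text, 20)

    def test_category_inference_and_override(self):
        text = (
            "gene\tstrand\tstart\tend\tcategory\n"
            "trnX\t+\t1\t5\t.\n"
            "rrnX\t-\t6\t9\t.\n"
            "NC9\t.\t10\t12\t.\n"
            "odd\t+\t13\t15\ttRNA\n"
        )
        ann = parse_annotation(text, 20)
        cats = {f.name: f.category for f in ann}
        assert cats == {
            "trnX": "tRNA",
            "rrnX": "rRNA",
            "NC9": "NC",
            "odd": "tRNA",
        }

    def test_round_trip_identity(self, gene_table):
        assert (
            parse_annotation(write_annotation(gene_table), GENOME_LENGTH)
            == gene_table
        )


class TestCoordinateArithmetic:
    @pytest.mark.parametrize(
        "gene,length",
        [("nad5", 1701), ("cox1", 1557), ("NC1", 442), ("rrnS", 740)],
    )
    def test_feature_lengths(self, gene_table, gene, length):
        assert feature_length(gene_table.feature(gene)) == length

    def test_cox1_length_divisible_by_three(self, gene_table):
        assert feature_length(gene_table.feature("cox1")) % 3 == 0

    def test_single_position_feature(self):
        f = GeneFeature("x", "tRNA", "+", 5, 5)
        assert feature_length(f) == 1

    @pytest.mark.parametrize(
        "prev,next_,value",
        [
            ("atp6", "trnR", 49),  # gap
            ("cox3", "trnG", -54),  # tRNA nested inside the gene upstream
            ("nad6", "nad2", 0),  # abutting
            ("cox1", "cox2", -26),  # same-strand overlap
        ],
    )
    def test_intergenic_values(self, gene_table, prev, next_, value):
        assert (
            intergenic_value(
                gene_table.feature(prev), gene_table.feature(next_),
                GENOME_LENGTH,
            )
            == value
        )

    def test_wrap_pair_counts_terminal_gap(self, gene_table):
        # positions 14851..14983 lie between rrnS and the cox1 start
        rrnS, cox1 = gene_table.feature("rrnS"), gene_table.feature("cox1")
        explicit = sum(
            1 for p in range(1, GENOME_LENGTH + 1) if p > rrnS.end
        )
        assert intergenic_value(rrnS, cox1, GENOME_LENGTH) == explicit == 133

    def test_genome_shorter_than_feature_rejected(self):
        a = GeneFeature("a", "PCG", "+", 1, 50)
        b = GeneFeature("b", "PCG", "+", 60, 80)
        with pytest.raises(RangeError):
            intergenic_value(a, b, 40)

    @given(
        L=st.integers(10, 50),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_positive_gap_equals_uncovered_positions(self, L, data):
        """A positive spacer equals the brute-force count of positions
        covered by neither feature between them, on circles up to 50 nt."""
        s1 = data.draw(st.integers(1, L // 2 - 1))
        e1 = data.draw(st.integers(s1, L // 2))
        s2 = data.draw(st.integers(e1 + 1, L))
        e2 = data.draw(st.integers(s2, L))
        a = GeneFeature("a", "PCG", "+", s1, e1)
        b = GeneFeature("b", "PCG", "+", s2, e2)
        gap = intergenic_value(a, b, L)
        explicit = sum(1 for p in range(e1 + 1, s2))
        assert gap == explicit
        wrap_gap = intergenic_value(b, a, L)
        explicit_wrap = (L - e2) + (s1 - 1)
        assert wrap_gap == explicit_wrap

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_length_plus_spacer_sums_to_genome_length(self, data):
        """Sum over consecutive pairs of next-length + spacer = L, for any
        sorted feature set, overlapping or not."""
        L = data.draw(st.integers(20, 200))
        n = data.draw(st.integers(1, 8))
        rows = []
        for i in range(n):
            s = data.draw(st.integers(1, L))
            e = data.draw(st.integers(s, L))
            rows.append((f"g{i}", "+", s, e))
        ann = toy_annotation(L, rows)
        pairs = ann.consecutive_pairs()
        total = sum(
            feature_length(nxt)
            + intergenic_value(prv, nxt, L, wrap=(i == len(pairs) - 1))
            for i, (prv, nxt) in enumerate(pairs)
        )
        if len(ann) == 1:
            (f,) = ann.features
            total = feature_length(f) + intergenic_value(f, f, L)
        assert total == L


class TestValidation:
    def test_known_discrepancies_flagged(self, gene_table):
        report = validate_annotation(gene_table)
        assert not report.ok
        by_field = {(w.feature, w.field): w for w in report.warnings}
        w = by_field[("nad6", "length")]
        assert (w.printed, w.recomputed) == (464, 465)
        w = by_field[("cox2", "intergenic")]
        assert (w.printed, w.recomputed) == (-23, -26)
        w = by_field[("nad4l", "intergenic")]
        assert (w.printed, w.recomputed) == (-8, -7)

    def test_self_consistent_table_is_clean(self):
        text = (
            "gene\tstrand\tstart\tend\tlength\tintergenic\n"
            "a\t+\t1\t6\t6\t+5\n"
            "b\t-\t10\t15\t6\t+3\n"
        )
        ann = parse_annotation(text, 20)
        assert validate_annotation(ann).ok

    def test_validation_never_mutates(self, gene_table):
        before = gene_table.features
        validate_annotation(gene_table)
        assert gene_table.features == before


class TestRotation:
    def test_rotation_preserves_lengths_and_spacers(self, gene_table):
        # rotate into the terminal gap so no feature is split
        rot = rotate_annotation(gene_table, 40)
        assert sorted(feature_length(f) for f in rot) == sorted(
            feature_length(f) for f in gene_table
        )

    def test_rotation_splitting_a_feature_is_rejected(self):
        ann = toy_annotation(10, [("a", "+", 2, 5)])
        with pytest.raises(CoordinateError):
            rotate_annotation(ann, 7)
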