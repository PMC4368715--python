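"""Non-coding region enumeration, coverage accounting and AT-enrichment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoprofile import (
    CompositionProfile,
    at_enrichment_test,
    coverage_breakdown,
    enumerate_noncoding,
    propose_control_regions,
)
from mitoprofile.annotation import rotate_annotation
from mitoprofile.errors import UndefinedStatisticError

from .conftest import (
    coverage_oracle,
    pearson_gof_oracle,
    contingency_oracle,
    toy_annotation,
)

GENOME_PROFILE = CompositionProfile.from_fractions(
    a=38.96, c=23.90, g=12.08, t=25.06
)


class TestEnumerateNoncoding:
    def test_bundled_table_includes_nc1(self, gene_table):
        regions = {
            (r.start, r.end): r for r in enumerate_noncoding(gene_table)
        }
        nc1 = regions[(7973, 8414)]
        assert nc1.length == 442
        assert nc1.source == "annotated-NC" and nc1.name == "NC1"

    def test_bundled_table_includes_49nt_gap(self, gene_table):
        regions = enumerate_noncoding(gene_table)
        gap = next(r for r in regions if r.start == 9282)
        assert gap.length == 49 and gap.source == "derived-gap"

    def test_full_cover_yields_empty_list(self):
        ann = toy_annotation(10, [("a", "+", 1, 10)])
        assert enumerate_noncoding(ann) == []

    def test_rotation_equivariance(self, gene_table):
        k = 40  # rotates into the terminal gap, splitting no feature
        L = gene_table.genome_length
        rotated = rotate_annotation(gene_table, k)
        base = {
            ((r.start - 1 + k) % L + 1, r.length)
            for r in enumerate_noncoding(gene_table)
        }
        moved = {
            (r.start, r.length) for r in enumerate_noncoding(rotated)
        }
        assert base == moved

    def test_lengths_complement_union_coverage(self, gene_table):
        cov = coverage_breakdown(gene_table)
        total_nc = sum(r.length for r in enumerate_noncoding(gene_table))
        assert cov.coding_bases + total_nc == gene_table.genome_length


class TestCoverage:
    def test_half_covered_circle(self):
        ann = toy_annotation(10, [("a", "+", 1, 5)])
        assert coverage_breakdown(ann).coding_fraction == 50.0

    def test_hand_counted_overlap(self):
        ann = toy_annotation(10, [("a", "+", 1, 5), ("b", "+", 4, 8)])
        cov = coverage_breakdown(ann)
        assert cov.coding_fraction == 80.0
        assert cov.overlap_bases == 2

    def test_fractions_partition_exactly(self, gene_table):
        cov = coverage_breakdown(gene_table)
        assert cov.coding_fraction + cov.noncoding_fraction == 100.0

    def test_bundled_table_matches_position_oracle(self, gene_table):
        cov = coverage_breakdown(gene_table)
        oracle = coverage_oracle(gene_table)
        assert cov.coding_bases == oracle["coding"]
        assert cov.overlap_bases == oracle["overlap"]
        assert cov.category_bases == oracle["per_cat_union"]
        both = coverage_breakdown(gene_table, "per-category-with-overlap")
        assert both.category_bases == oracle["per_cat_overlapping"]

    @given(data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_random_annotations_match_position_oracle(self, data):
        L = data.draw(st.integers(20, 120))
        n = data.draw(st.integers(1, 10))
        rows = []
        for i in range(n):
            s = data.draw(st.integers(1, L))
            e = data.draw(st.integers(s, L))
            kind = data.draw(st.sampled_from(["g", "trn", "rrn"]))
            rows.append((f"{kind}{i}", "+", s, e))
        ann = toy_annotation(L, rows)
        cov = coverage_breakdown(ann)
        oracle = coverage_oracle(ann)
        assert cov.coding_bases == oracle["coding"]
        assert cov.overlap_bases == oracle["overlap"]
        assert cov.category_bases == oracle["per_cat_union"]
        total_nc = sum(r.length for r in enumerate_noncoding(ann))
        assert total_nc == oracle["noncoding"]


class TestEnrichment:
    def test_nc1_counts_give_published_scale_statistic(self):
        """Region counts from the printed NC1 AT% (71.27% of 442 nt) give
        chi2 ~ 10.08 against the genome-wide AT fraction."""
        res = at_enrichment_test((315, 127), GENOME_PROFILE, "gof")
        assert res.chi2 == pytest.approx(10.078, abs=0.01)
        assert res.df == 1
        assert res.significant(0.01)

    def test_proportional_counts_give_zero(self):
        profile = CompositionProfile(a=32, c=18, g=18, t=32)
        res = at_enrichment_test((64, 36), profile, "gof")
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1.0)

    def test_doubling_counts_doubles_statistic(self):
        r1 = at_enrichment_test((300, 120), GENOME_PROFILE, "gof")
        r2 = at_enrichment_test((600, 240), GENOME_PROFILE, "gof")
        assert r2.chi2 == pytest.approx(2 * r1.chi2, rel=1e-9)

    @pytest.mark.parametrize("at,gc", [(315, 127), (280, 114), (30, 20)])
    def test_gof_matches_textbook_formula(self, at, gc):
        p_at = (GENOME_PROFILE.a + GENOME_PROFILE.t) / GENOME_PROFILE.total
        res = at_enrichment_test((at, gc), GENOME_PROFILE, "gof")
        assert res.chi2 == pytest.approx(
            pearson_gof_oracle(at, gc, p_at), rel=1e-12
        )

    @pytest.mark.parametrize("at,gc", [(315, 127), (50, 60)])
    def test_contingency_matches_first_principles(self, at, gc):
        genome = CompositionProfile(a=5000, c=1800, g=1200, t=4000)
        res = at_enrichment_test((at, gc), genome, "contingency-2x2")
        rest_at = genome.a + genome.t - at
        rest_gc = genome.g + genome.c - gc
        assert res.chi2 == pytest.approx(
            contingency_oracle(at, gc, rest_at, rest_gc), rel=1e-9
        )

    def test_yates_is_smaller_than_uncorrected(self):
        r = at_enrichment_test((315, 127), GENOME_PROFILE, "gof")
        ry = at_enrichment_test((315, 127), GENOME_PROFILE, "gof-yates")
        assert 0 < ry.chi2 < r.chi2
        genome = CompositionProfile(a=5000, c=1800, g=1200, t=4000)
        rc = at_enrichment_test((315, 127), genome, "contingency-2x2")
        rcy = at_enrichment_test((315, 127), genome, "contingency-yates")
        assert 0 < rcy.chi2 < rc.chi2

    def test_empty_region_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            at_enrichment_test((0, 0), GENOME_PROFILE)

    def test_degenerate_genome_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            at_enrichment_test((10, 5), CompositionProfile(a=5, c=0, g=0, t=5))


class TestProposal:
    def test_planted_regions_recovered(self, simulated):
        seq, ann, _ = simulated
        found = propose_control_regions(ann, seq, alpha=0.01, min_len=200)
        assert {r.name for r, _ in found} == {"NC1", "NC2"}

    def test_min_len_larger_than_everything(self, simulated):
        seq, ann, _ = simulated
        assert propose_control_regions(ann, seq, min_len=10_000) == []

    def test_bonferroni_is_more_conservative(self, simulated):
        seq, ann, _ = simulated
        plain = propose_control_regions(ann, seq, alpha=0.05, min_len=10)
        bonf = propose_control_regions(
            ann, seq, alpha=0.05, min_len=10, bonferroni=True
        )
        assert len(bonf) <= len(plain)
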