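"""Non-coding region enumeration, coverage accounting and AT-enrichment tests.

Non-coding positions are those covered by no PCG/rRNA/tRNA feature.
Coverage uses exact interval (sweep-line) arithmetic on the circle, so
union coverage plus the summed non-coding region lengths always equals the
genome length.

AT enrichment of a candidate control region is tested with a Pearson
chi-square on its (A+T, G+C) counts, either as a 1-df goodness-of-fit
against the genome-wide A+T fraction or as a 2x2 contingency table of
region vs rest-of-genome; Yates-corrected variants of both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .annotation import CircularAnnotation, GeneFeature, feature_intervals
from .composition import CompositionProfile, base_composition, extract_region
from .errors import UndefinedStatisticError

Variant = Literal["gof", "gof-yates", "contingency-2x2", "contingency-yates"]


@dataclass(frozen=True)
class NoncodingRegion:
    """A run of positions covered by no coding feature (may wrap the origin)."""

    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; start > end means the region wraps
    length: int
    source: str  # "annotated-NC" or "derived-gap"
    name: str | None = None

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        if self.start <= self.end:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (1, self.end)]


def _merged_coding_intervals(
    ann: CircularAnnotation,
) -> list[tuple[int, int]]:
    """Union of PCG/rRNA/tRNA intervals, merged, sorted, non-wrapping parts."""
    raw: list[tuple[int, int]] = []
    for f in ann:
        if not f.is_coding:
            continue
        raw.extend(feature_intervals(f, ann.genome_length))
    if not raw:
        return []
    raw.sort()
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def enumerate_noncoding(ann: CircularAnnotation) -> list[NoncodingRegion]:
    """Complement of the union of coding features on the circle.

    Regions coinciding with an annotated NC feature are labelled
    ``annotated-NC`` (carrying its name); all others are ``derived-gap``.
    The gap across the origin is included and reported as a wrapping region.
    """
    L = ann.genome_length
    merged = _merged_coding_intervals(ann)
    if not merged:
        return [NoncodingRegion(1, L, L, "derived-gap")]
    regions: list[tuple[int, int, int]] = []  # (start, end, length)
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if s2 > e1 + 1:
            regions.append((e1 + 1, s2 - 1, s2 - e1 - 1))
    # wrap gap between the last merged interval and the first
    first_s, _ = merged[0]
    _, last_e = merged[-1]
    wrap_len = (L - last_e) + (first_s - 1)
    if wrap_len > 0:
        start = last_e + 1 if last_e < L else 1
        end = first_s - 1 if first_s > 1 else L
        regions.append((start, end, wrap_len))
    nc_by_interval = {
        (f.start, f.end): f.name for f in ann if f.category == "NC"
    }
    out = []
    for s, e, ln in sorted(regions):
        name = nc_by_interval.get((s, e))
        out.append(
            NoncodingRegion(
                s,
                e,
                ln,
                "annotated-NC" if name else "derived-gap",
                name,
            )
        )
    return out


@dataclass(frozen=True)
class CoverageBreakdown:
    """Coding/non-coding split of the circle under an explicit overlap rule.

    ``attribution="union"``: every position counts once; positions covered
    by features of several categories are attributed by the fixed priority
    PCG > rRNA > tRNA, so category fractions sum to 100% of coding DNA.
    ``attribution="per-category-with-overlap"``: a position covered by
    features of two categories counts toward both, so category fractions
    can sum to more than 100%.
    """

    genome_length: int
    attribution: str
    coding_bases: int
    overlap_bases: int
    category_bases: dict[str, int]

    @property
    def coding_fraction(self) -> float:
        return 100.0 * self.coding_bases / self.genome_length

    @property
    def noncoding_fraction(self) -> float:
        return 100.0 - self.coding_fraction

    def category_fraction_of_coding(self, category: str) -> float:
        if self.coding_bases == 0:
            raise UndefinedStatisticError("no coding bases")
        return 100.0 * self.category_bases[category] / self.coding_bases


def coverage_breakdown(
    ann: CircularAnnotation, attribution: str = "union"
) -> CoverageBreakdown:
    """Exact coverage accounting by sweep-line over interval endpoints."""
    if attribution not in {"union", "per-category-with-overlap"}:
        raise ValueError(f"unknown attribution rule {attribution!r}")
    L = ann.genome_length
    # events per category at each breakpoint position
    categories = ("PCG", "rRNA", "tRNA")
    deltas: dict[int, dict[str, int]] = {}
    for f in ann:
        if not f.is_coding:
            continue
        for s, e in feature_intervals(f, L):
            deltas.setdefault(s, {}).setdefault(f.category, 0)
            deltas[s][f.category] = deltas[s].get(f.category, 0) + 1
            deltas.setdefault(e + 1, {}).setdefault(f.category, 0)
            deltas[e + 1][f.category] = deltas[e + 1].get(f.category, 0) - 1
    coding = 0
    overlap = 0
    cat_bases = {c: 0 for c in categories}
    depth = {c: 0 for c in categories}
    positions = sorted(deltas)
    for i, pos in enumerate(positions):
        for c, d in deltas[pos].items():
            depth[c] += d
        nxt = positions[i + 1] if i + 1 < len(positions) else L + 1
        span = max(0, min(nxt, L + 1) - pos)
        if span == 0:
            continue
        total_depth = sum(depth.values())
        if total_depth == 0:
            continue
        coding += span
        if total_depth >= 2:
            overlap += span
        if attribution == "union":
            for c in categories:  # priority order PCG > rRNA > tRNA
                if depth[c] > 0:
                    cat_bases[c] += span
                    break
        else:
            for c in categories:
                if depth[c] > 0:
                    cat_bases[c] += span
    return CoverageBreakdown(
        genome_length=L,
        attribution=attribution,
        coding_bases=coding,
        overlap_bases=overlap,
        category_bases=cat_bases,
    )


@dataclass(frozen=True)
class EnrichmentTestResult:
    chi2: float
    df: int
    pvalue: float
    variant: str

    def significant(self, alpha: float = 0.01) -> bool:
        return self.pvalue < alpha


def at_enrichment_test(
    region_counts: tuple[int, int],
    genome_profile: CompositionProfile,
    variant: Variant = "gof",
) -> EnrichmentTestResult:
    """Chi-square test of a region's AT/GC counts against the genome.

    ``region_counts`` is (A+T, G+C) for the region.  The goodness-of-fit
    variants compare the region against expectations from the genome-wide
    A+T fraction; the contingency variants build a 2x2 table of region vs
    rest-of-genome.  Yates variants apply the continuity correction.
    """
    at, gc = (int(region_counts[0]), int(region_counts[1]))
    n = at + gc
    if n < 1:
        raise UndefinedStatisticError("region has no unambiguous bases")
    g_at = genome_profile.a + genome_profile.t
    g_gc = genome_profile.g + genome_profile.c
    g_total = g_at + g_gc
    if g_at == 0 or g_gc == 0:
        raise UndefinedStatisticError(
            "genome AT and GC fractions must both be in (0,1)"
        )
    p_at = g_at / g_total
    if variant in {"gof", "gof-yates"}:
        expected = np.array([n * p_at, n * (1 - p_at)])
        if np.any(expected == 0):
            raise UndefinedStatisticError("zero expected count")
        observed = np.array([at, gc], dtype=float)
        if variant == "gof":
            chi2, p = stats.chisquare(observed, expected)
        else:
            dev = np.abs(observed - expected) - 0.5
            dev = np.maximum(dev, 0.0)
            chi2 = float(np.sum(dev**2 / expected))
            p = float(stats.chi2.sf(chi2, df=1))
        return EnrichmentTestResult(float(chi2), 1, float(p), variant)
    if variant in {"contingency-2x2", "contingency-yates"}:
        rest_at, rest_gc = g_at - at, g_gc - gc
        if min(rest_at, rest_gc) < 0:
            raise UndefinedStatisticError(
                "region counts exceed genome counts; pass the whole-genome "
                "profile, not the region's"
            )
        table = np.array([[at, gc], [rest_at, rest_gc]], dtype=float)
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            raise UndefinedStatisticError("zero expected count in 2x2 table")
        res = stats.chi2_contingency(
            table, correction=(variant == "contingency-yates")
        )
        return EnrichmentTestResult(
            float(res.statistic), 1, float(res.pvalue), variant
        )
    raise ValueError(f"unknown test variant {variant!r}")


def propose_control_regions(
    ann: CircularAnnotation,
    seq: str,
    alpha: float = 0.01,
    min_len: int = 200,
    variant: Variant = "gof",
    bonferroni: bool = False,
) -> list[tuple[NoncodingRegion, EnrichmentTestResult]]:
    """Non-coding regions proposed as control regions.

    A region qualifies when its length is at least ``min_len``, its A+T
    content exceeds the genome's, and its enrichment test is significant at
    ``alpha``.  ``min_len`` defaults to 200 nt so that only regions long
    enough for a reasonably powered test are considered; ``bonferroni``
    divides alpha by the number of regions actually tested (off by default).
    """
    genome = base_composition(seq)
    regions = enumerate_noncoding(ann)
    candidates = [r for r in regions if r.length >= min_len]
    if not candidates:
        return []
    eff_alpha = alpha / len(candidates) if bonferroni else alpha
    out = []
    for region in candidates:
        piece = "".join(
            extract_region(seq, s, e) for s, e in region.intervals(len(seq))
        )
        prof = base_composition(piece)
        at = prof.a + prof.t
        gc = prof.g + prof.c
        result = at_enrichment_test((at, gc), genome, variant)
        if prof.at_content > genome.at_content and result.pvalue < eff_alpha:
            out.append((region, result))
    return out
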