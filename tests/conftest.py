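"""Shared fixtures: bundled tables, simulated genomes, compact skeletons."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

# fully reproducible property tests, no example database
_hyp_settings.register_profile("deterministic", derandomize=True,
                               database=None)
_hyp_settings.load_profile("deterministic")

from mitoprofile import (
    CircularAnnotation,
    GeneFeature,
    default_spec,
    load_bundled_annotation,
    load_bundled_codon_table,
    simulate_genome,
)
from mitoprofile.synthetic import (
    DEFAULT_CATEGORY_COMPOSITION,
    SyntheticGenomeSpec,
    _category_fractions,
)

GENOME_LENGTH = 14983


@pytest.fixture(scope="session")
def gene_table() -> CircularAnnotation:
    return load_bundled_annotation()


@pytest.fixture(scope="session")
def codon_table():
    return load_bundled_codon_table()


@pytest.fixture(scope="session")
def simulated():
    """One default-spec genome, shared across tests (seed fixed)."""
    return simulate_genome(default_spec(seed=20240901))


def toy_annotation(
    L: int, rows: list[tuple[str, str, int, int]]
) -> CircularAnnotation:
    feats = tuple(
        GeneFeature(
            name=n,
            category=(
                "tRNA"
                if n.startswith("trn")
                else "NC"
                if n.startswith("NC")
                else "rRNA"
                if n.startswith("rrn")
                else "PCG"
            ),
            strand=s,
            start=a,
            end=b,
        )
        for n, s, a, b in rows
    )
    return CircularAnnotation(L, feats)


def compact_spec(
    seed: int, nc_at_percent: float, mode: str
) -> SyntheticGenomeSpec:
    """A 3 kb circle with two 400-nt NC regions, for Monte-Carlo studies."""
    table = load_bundled_codon_table()
    weights = {
        c: float(v)
        for c, v in table.counts.items()
        if table.code.mapping[c] != "*" and v > 0
    }
    feats = (
        GeneFeature("p1", "PCG", "+", 1, 900),
        GeneFeature("t1", "tRNA", "+", 931, 1000),
        GeneFeature("NCa", "NC", ".", 1001, 1400),
        GeneFeature("p2", "PCG", "-", 1401, 2300),
        GeneFeature("NCb", "NC", ".", 2351, 2750),
        GeneFeature("t2", "tRNA", "-", 2801, 2870),
    )
    comp = dict(DEFAULT_CATEGORY_COMPOSITION)
    comp["NC"] = _category_fractions(nc_at_percent)
    return SyntheticGenomeSpec(
        genome_length=3000,
        features=feats,
        codon_weights=weights,
        start_pool={"ATT": 1, "ATG": 1},
        stop_pool={"TAA": 1, "TAG": 1},
        category_composition=comp,
        mode=mode,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Independent oracles (deliberately brute-force; never share code with the
# implementation paths they check)
# ---------------------------------------------------------------------------


def coverage_oracle(ann: CircularAnnotation) -> dict:
    """Per-position marking over the whole circle."""
    L = ann.genome_length
    depth = {c: np.zeros(L, dtype=int) for c in ("PCG", "rRNA", "tRNA")}
    for f in ann:
        if f.category == "NC":
            continue
        if f.spans_origin:
            spans = [(f.start, L), (1, f.end)]
        else:
            spans = [(f.start, f.end)]
        for s, e in spans:
            depth[f.category][s - 1 : e] += 1
    total = sum(depth.values())
    coding = int((total > 0).sum())
    overlap = int((total > 1).sum())
    per_cat_overlapping = {c: int((d > 0).sum()) for c, d in depth.items()}
    # union-priority attribution: PCG > rRNA > tRNA
    per_cat_union = {}
    claimed = np.zeros(L, dtype=bool)
    for c in ("PCG", "rRNA", "tRNA"):
        here = (depth[c] > 0) & ~claimed
        per_cat_union[c] = int(here.sum())
        claimed |= depth[c] > 0
    return {
        "coding": coding,
        "overlap": overlap,
        "per_cat_union": per_cat_union,
        "per_cat_overlapping": per_cat_overlapping,
        "noncoding": L - coding,
    }


def breakpoint_oracle(order1, order2) -> int:
    """Count o1 adjacencies absent from o2 by explicit scanning of o2 in
    both reading directions."""
    common = order1.labels & order2.labels
    g1 = [(g, s) for g, s in order1.genes if g in common]
    g2 = [(g, s) for g, s in order2.genes if g in common]
    n, m = len(g1), len(g2)
    count = 0
    for i in range(n):
        x, y = g1[i], g1[(i + 1) % n]
        found = False
        for j in range(m):
            a, b = g2[j], g2[(j + 1) % m]
            if a == x and b == y:
                found = True
                break
            if (
                a[0] == y[0]
                and a[1] == -y[1]
                and b[0] == x[0]
                and b[1] == -x[1]
            ):
                found = True
                break
        if not found:
            count += 1
    return count


def pearson_gof_oracle(at: int, gc: int, p_at: float) -> float:
    n = at + gc
    e_at, e_gc = n * p_at, n * (1 - p_at)
    return (at - e_at) ** 2 / e_at + (gc - e_gc) ** 2 / e_gc


def contingency_oracle(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi2 of a 2x2 table [[a,b],[c,d]] from first principles."""
    n = a + b + c + d
    chi2 = 0.0
    for obs, row, col in (
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ):
        exp = row * col / n
        chi2 += (obs - exp) ** 2 / exp
    return chi2
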