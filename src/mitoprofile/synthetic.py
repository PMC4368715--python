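"""Seeded generation of annotated circular mitogenomes, and gene-order
perturbation, so every pipeline stage is testable without external data.

The default specification emulates a geophilomorph-centipede-like molecule:
a 14,983 bp circle carrying 13 protein-coding genes, 2 rRNAs, 16 tRNAs and
two large AT-rich non-coding regions, with the coordinate skeleton (including
same-strand and opposite-strand overlaps) of the bundled gene table.
Protein-coding genes are built as an assigned initiation codon, interior
codons drawn from the bundled codon-usage distribution (stop codons
excluded), and an assigned termination codon; RNA and non-coding regions are
filled from per-category base-composition targets.

Two sampling modes exist:

* ``exact`` (default): interior codons are dealt from a deck whose codon
  counts follow the target distribution by largest-remainder apportionment,
  and region base counts are exact apportionments of the composition target.
  Censuses and compositions are then deterministic up to overlap repairs.
* ``probabilistic``: i.i.d. multinomial draws; used for calibration studies
  where sampling noise must be present.

Reproducibility is mandatory: a spec without a seed is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import (
    CircularAnnotation,
    GeneFeature,
    feature_intervals,
    feature_length,
    intergenic_value,
)
from .codons import (
    ALL_CODONS,
    GeneticCode,
    invertebrate_mito_code,
    load_bundled_codon_table,
)
from .composition import reverse_complement
from .errors import InfeasibleSpecError
from .geneorder import Signed, SignedGeneOrder

#: RNG algorithm used throughout; named so that seeds are portable.
RNG_ALGORITHM = "numpy.random.Generator(PCG64)"

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Plus-strand composition targets (A, C, G, T fractions). The non-PCG
# defaults share the A:T and C:G ratios of the target plus strand
# (A 38.96 / T 25.06 / C 23.90 / G 12.08 percent) at each category's A+T
# level: 68.58% for rRNA (the published rRNA average), 71% for the two
# control-region stand-ins, and 64.02% (the whole-genome value) for tRNAs
# and intergenic spacers.
_AT_RATIO_A = 38.96 / 64.02
_GC_RATIO_C = 23.90 / 35.98


def _category_fractions(at_percent: float) -> tuple[float, float, float, float]:
    at = at_percent / 100.0
    gc = 1.0 - at
    a = at * _AT_RATIO_A
    t = at - a
    c = gc * _GC_RATIO_C
    g = gc - c
    return (a, c, g, t)


DEFAULT_CATEGORY_COMPOSITION: dict[str, tuple[float, float, float, float]] = {
    "rRNA": _category_fractions(68.58),
    "tRNA": _category_fractions(64.02),
    "NC": _category_fractions(71.0),
    "gap": _category_fractions(64.02),
}

#: Default initiation-codon pool (codon -> count over the 13 PCGs).
DEFAULT_START_POOL = {"ATT": 5, "ATG": 5, "ATA": 2, "ATC": 1}
#: Default termination-codon pool.
DEFAULT_STOP_POOL = {"TAA": 8, "TAG": 5}


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Everything needed to generate one annotated circular genome."""

    genome_length: int
    features: tuple[GeneFeature, ...]
    codon_weights: Mapping[str, float]  # interior codon distribution
    start_pool: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_START_POOL)
    )
    stop_pool: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STOP_POOL)
    )
    category_composition: Mapping[str, tuple[float, float, float, float]] = (
        field(default_factory=lambda: dict(DEFAULT_CATEGORY_COMPOSITION))
    )
    mode: str = "exact"  # "exact" | "probabilistic"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"exact", "probabilistic"}:
            raise InfeasibleSpecError(f"unknown mode {self.mode!r}")
        for cat, fracs in self.category_composition.items():
            if abs(sum(fracs) - 1.0) > 1e-6:
                raise InfeasibleSpecError(
                    f"{cat}: composition fractions must sum to 1"
                )
            if any(x < 0 for x in fracs):
                raise InfeasibleSpecError(f"{cat}: negative fraction")

    def to_json(self) -> str:
        return json.dumps(
            {
                "rng": RNG_ALGORITHM,
                "genome_length": self.genome_length,
                "mode": self.mode,
                "seed": self.seed,
                "start_pool": dict(self.start_pool),
                "stop_pool": dict(self.stop_pool),
                "codon_weights": dict(self.codon_weights),
                "category_composition": {
                    k: list(v) for k, v in self.category_composition.items()
                },
                "features": [
                    {
                        "name": f.name,
                        "category": f.category,
                        "strand": f.strand,
                        "start": f.start,
                        "end": f.end,
                        "start_codon": f.printed_start_codon,
                        "stop_codon": f.printed_stop_codon,
                    }
                    for f in self.features
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticGenomeSpec":
        raw = json.loads(text)
        features = tuple(
            GeneFeature(
                name=d["name"],
                category=d["category"],
                strand=d["strand"],
                start=d["start"],
                end=d["end"],
                printed_start_codon=d.get("start_codon"),
                printed_stop_codon=d.get("stop_codon"),
            )
            for d in raw["features"]
        )
        return cls(
            genome_length=raw["genome_length"],
            features=features,
            codon_weights=raw["codon_weights"],
            start_pool=raw.get("start_pool", dict(DEFAULT_START_POOL)),
            stop_pool=raw.get("stop_pool", dict(DEFAULT_STOP_POOL)),
            category_composition={
                k: tuple(v)
                for k, v in raw.get(
                    "category_composition", DEFAULT_CATEGORY_COMPOSITION
                ).items()
            },
            mode=raw.get("mode", "exact"),
            seed=raw.get("seed"),
        )


def default_spec(seed: int | None = None) -> SyntheticGenomeSpec:
    """The centipede-mitogenome-like default specification.

    Skeleton coordinates, strands and per-gene start/stop codon assignments
    come from the bundled gene table; the interior codon distribution is the
    bundled codon-usage census with stop codons removed.
    """
    from .annotation import load_bundled_annotation

    ann = load_bundled_annotation()
    table = load_bundled_codon_table()
    code = table.code
    weights = {
        c: float(v)
        for c, v in table.counts.items()
        if code.mapping[c] != "*" and v > 0
    }
    return SyntheticGenomeSpec(
        genome_length=ann.genome_length,
        features=ann.features,
        codon_weights=weights,
        seed=seed,
    )


@dataclass
class TruthRecord:
    """Ground truth of one simulation, sufficient to audit every region."""

    seed: int
    mode: str
    rng: str = RNG_ALGORITHM
    start_codons: dict = field(default_factory=dict)  # gene -> codon
    stop_codons: dict = field(default_factory=dict)
    interior_codons: dict = field(default_factory=dict)  # gene -> list[str]
    region_composition: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "mode": self.mode,
                "rng": self.rng,
                "start_codons": self.start_codons,
                "stop_codons": self.stop_codons,
                "interior_codons": self.interior_codons,
                "region_composition": self.region_composition,
                "warnings": self.warnings,
            }
        )


def _apportion(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items over weighted keys."""
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise InfeasibleSpecError("weights must sum to > 0")
    quota = n * w / w.sum()
    base = np.floor(quota).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(quota - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return {k: int(b) for k, b in zip(keys, base)}


def _deal_pool(
    pool: Mapping[str, float], n: int, rng: np.random.Generator, mode: str
) -> list[str]:
    """Assign n codons from a pool: exact apportionment or multinomial."""
    keys = sorted(pool)
    if mode == "exact":
        counts = _apportion(pool, n)
        deck = [k for k in keys for _ in range(counts[k])]
    else:
        p = np.array([pool[k] for k in keys], dtype=float)
        p = p / p.sum()
        deck = [keys[i] for i in rng.choice(len(keys), size=n, p=p)]
    rng.shuffle(deck)
    return deck


def _plus_strand_codon_positions(
    f: GeneFeature, L: int
) -> list[tuple[int, ...]]:
    """Plus-strand (0-based) position triples of each codon, reading order."""
    positions: list[int] = []
    for s, e in feature_intervals(f, L):
        positions.extend(range(s - 1, e))
    if f.strand == "-":
        positions = positions[::-1]
    n_full = len(positions) // 3
    return [tuple(positions[3 * i : 3 * i + 3]) for i in range(n_full)]


def _write_codon(
    arr: np.ndarray, triple: tuple[int, ...], codon: str, strand: str
) -> None:
    for pos, base in zip(triple, codon):
        arr[pos] = _BASES.index(
            base if strand == "+" else _COMPLEMENT[base]
        )


def _read_codon(arr: np.ndarray, triple: tuple[int, ...], strand: str) -> str:
    out = []
    for pos in triple:
        v = arr[pos]
        if v < 0:
            return ""
        b = _BASES[v]
        out.append(b if strand == "+" else _COMPLEMENT[b])
    return "".join(out)


def _fixed_pattern(
    arr: np.ndarray,
    pinned: np.ndarray,
    triple: tuple[int, ...],
    strand: str,
    respect_filled: bool,
) -> str:
    """Pattern of a codon slot: fixed bases or '.' where free."""
    out = []
    for pos in triple:
        fixed = pinned[pos] or (respect_filled and arr[pos] >= 0)
        if fixed and arr[pos] >= 0:
            b = _BASES[arr[pos]]
            out.append(b if strand == "+" else _COMPLEMENT[b])
        else:
            out.append(".")
    return "".join(out)


def _matching_codons(pattern: str, candidates: Iterable[str]) -> list[str]:
    return [
        c
        for c in candidates
        if all(p == "." or p == b for p, b in zip(pattern, c))
    ]


def simulate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[str, CircularAnnotation, TruthRecord]:
    """Generate (sequence, annotation, truth record) from a seeded spec.

    Overlap handling: the shared segment is generated once by the feature
    that comes first in start order; a later feature's constrained codons
    are sampled conditionally on the already-fixed bases, and a repair pass
    resolves cross-frame stop codons.  An overlap whose constraints cannot
    be satisfied is left in place with a warning in the truth record.
    """
    if spec.seed is None:
        raise InfeasibleSpecError(
            "spec.seed is required; reproducibility is mandatory"
        )
    L = spec.genome_length
    feats = tuple(sorted(spec.features, key=lambda f: (f.start, f.end, f.name)))
    for f in feats:
        if max(f.start, f.end) > L:
            raise InfeasibleSpecError(
                f"{f.name}: coordinates exceed genome length {L}"
            )
    pcgs = [f for f in feats if f.category == "PCG"]
    for f in pcgs:
        if feature_length(f, L) < 9:
            raise InfeasibleSpecError(
                f"{f.name}: a PCG needs >= 9 nt (start + 1 codon + stop)"
            )
    code = invertebrate_mito_code()
    stop_codons = set(code.stop_codons)
    nonstop = [c for c in ALL_CODONS if c not in stop_codons]
    weights = {c: float(w) for c, w in spec.codon_weights.items() if w > 0}
    if set(weights) & stop_codons:
        raise InfeasibleSpecError(
            "interior codon weights must not contain stop codons"
        )

    rng = np.random.default_rng(spec.seed)
    truth = TruthRecord(seed=spec.seed, mode=spec.mode)
    arr = np.full(L, -1, dtype=np.int8)
    pinned = np.zeros(L, dtype=bool)

    # ------------------------------------------------------------------ 1.
    # Assign and pin start/stop codons.  Per-gene printed codons in the
    # skeleton take precedence; remaining genes draw from the pools.
    needs_start = [f for f in pcgs if not f.printed_start_codon]
    needs_stop = [f for f in pcgs if not f.printed_stop_codon]
    start_deck = _deal_pool(spec.start_pool, len(needs_start), rng, spec.mode)
    stop_deck = _deal_pool(spec.stop_pool, len(needs_stop), rng, spec.mode)
    assigned_start = {
        f.name: f.printed_start_codon for f in pcgs if f.printed_start_codon
    }
    assigned_stop = {
        f.name: f.printed_stop_codon for f in pcgs if f.printed_stop_codon
    }
    for f, codon in zip(needs_start, start_deck):
        assigned_start[f.name] = codon
    for f, codon in zip(needs_stop, stop_deck):
        assigned_stop[f.name] = codon

    codon_slots = {f.name: _plus_strand_codon_positions(f, L) for f in pcgs}
    for f in pcgs:
        slots = codon_slots[f.name]
        for triple, codon in (
            (slots[0], assigned_start[f.name]),
            (slots[-1], assigned_stop[f.name]),
        ):
            for pos, base in zip(triple, codon):
                want = (
                    _BASES.index(base)
                    if f.strand == "+"
                    else _BASES.index(_COMPLEMENT[base])
                )
                if arr[pos] >= 0 and arr[pos] != want:
                    raise InfeasibleSpecError(
                        f"{f.name}: start/stop codon conflicts with an "
                        f"earlier pinned base at position {pos + 1}"
                    )
                arr[pos] = want
                pinned[pos] = True
        truth.start_codons[f.name] = assigned_start[f.name]
        truth.stop_codons[f.name] = assigned_stop[f.name]

    # ------------------------------------------------------------------ 2.
    # Interior codons, genes in start order; earlier features win overlaps.
    n_interior = sum(len(codon_slots[f.name]) - 2 for f in pcgs)
    if spec.mode == "exact":
        deck = _deal_pool(weights, n_interior, rng, "exact")
    else:
        deck = _deal_pool(weights, n_interior, rng, "probabilistic")
    deck_i = 0
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys])
    probs = probs / probs.sum()

    def conditional_codon(pattern: str) -> str | None:
        options = _matching_codons(pattern, keys)
        if not options:
            safe = _matching_codons(pattern, nonstop)
            if not safe:
                return None
            return safe[int(rng.integers(len(safe)))]
        w = np.array([weights[c] for c in options])
        return options[int(rng.choice(len(options), p=w / w.sum()))]

    for f in pcgs:
        interior = []
        for triple in codon_slots[f.name][1:-1]:
            pattern = _fixed_pattern(arr, pinned, triple, f.strand, True)
            if pattern == "...":
                codon = deck[deck_i]
                deck_i += 1
            elif "." not in pattern:
                codon = pattern  # fully fixed by an earlier feature
                if codon in stop_codons:
                    # leave for the repair pass
                    pass
            else:
                codon = conditional_codon(pattern)
                if codon is None:
                    truth.warnings.append(
                        f"{f.name}: overlap forces a stop codon; kept"
                    )
                    codon = pattern.replace(".", "A")
            _write_codon(arr, triple, codon, f.strand)
            interior.append(codon)
        truth.interior_codons[f.name] = interior

    # ------------------------------------------------------------------ 3.
    # Repair pass: remove stop codons that arose in another gene's frame
    # through overlap, resampling only non-pinned bases.
    for _sweep in range(50):
        dirty = False
        for f in pcgs:
            for triple in codon_slots[f.name][1:-1]:
                codon = _read_codon(arr, triple, f.strand)
                if codon not in stop_codons:
                    continue
                pattern = _fixed_pattern(arr, pinned, triple, f.strand, False)
                if "." not in pattern:
                    continue  # fully pinned; recorded below
                repl = conditional_codon(pattern)
                if repl is None or repl in stop_codons:
                    continue
                _write_codon(arr, triple, repl, f.strand)
                dirty = True
        if not dirty:
            break
    for f in pcgs:
        for k, triple in enumerate(codon_slots[f.name][1:-1], start=1):
            codon = _read_codon(arr, triple, f.strand)
            if codon in stop_codons:
                truth.warnings.append(
                    f"{f.name}: unresolvable internal stop at codon {k}"
                )

    # ------------------------------------------------------------------ 4.
    # RNA, non-coding and spacer fill from composition targets.
    def fill(positions: np.ndarray, fracs, label: str) -> None:
        if positions.size == 0:
            return
        comp = {b: fr for b, fr in zip(_BASES, fracs)}
        if spec.mode == "exact":
            counts = _apportion(comp, positions.size)
            bases = [
                _BASES.index(b) for b in sorted(counts) for _ in range(counts[b])
            ]
            bases = np.array(bases, dtype=np.int8)
            rng.shuffle(bases)
        else:
            p = np.array([comp[b] for b in _BASES])
            bases = rng.choice(4, size=positions.size, p=p / p.sum()).astype(
                np.int8
            )
        arr[positions] = bases

    for f in feats:
        if f.category == "PCG":
            continue
        fracs = spec.category_composition.get(f.category)
        if fracs is None:
            raise InfeasibleSpecError(
                f"no composition target for category {f.category}"
            )
        idx = np.concatenate(
            [
                np.arange(s - 1, e)
                for s, e in feature_intervals(f, L)
            ]
        )
        fill(idx[arr[idx] < 0], fracs, f.name)
    gap_positions = np.flatnonzero(arr < 0)
    fill(gap_positions, spec.category_composition.get("gap", (0.25,) * 4),
         "gap")

    seq = "".join(_BASES[v] for v in arr)

    # ------------------------------------------------------------------ 5.
    # Annotation with recomputed printed columns, and the truth record.
    ann_feats = []
    ordered = feats
    for i, f in enumerate(ordered):
        prev = ordered[i - 1]
        ann_feats.append(
            replace(
                f,
                printed_length=feature_length(f, L),
                printed_start_codon=assigned_start.get(f.name),
                printed_stop_codon=assigned_stop.get(f.name),
                printed_intergenic=(
                    intergenic_value(prev, f, L, wrap=(i == 0))
                    if len(ordered) > 1
                    else None
                ),
            )
        )
    ann = CircularAnnotation(
        L, tuple(ann_feats), source_notes=f"simulated (seed={spec.seed})"
    )
    for f in feats:
        idx = np.concatenate(
            [np.arange(s - 1, e) for s, e in feature_intervals(f, L)]
        )
        vals, counts = np.unique(arr[idx], return_counts=True)
        comp = {b: 0 for b in _BASES}
        for v, cnt in zip(vals, counts):
            comp[_BASES[v]] = int(cnt)
        truth.region_composition[f.name] = comp
    return seq, ann, truth


# ---------------------------------------------------------------------------
# Gene-order perturbation
# ---------------------------------------------------------------------------


def perturb_order(
    order: SignedGeneOrder,
    n_translocations: int,
    n_inversions: int,
    seed: int,
) -> tuple[SignedGeneOrder, list[dict]]:
    """Apply random single-gene translocations then segment inversions.

    Translocations remove one gene and reinsert it (orientation kept) at a
    uniformly chosen position; inversions reverse a uniformly chosen
    segment, flipping orientations.  The move log is sufficient to replay
    the perturbation with :func:`replay_moves`.
    """
    if len(order) < 3:
        raise ValueError("order must contain at least 3 genes")
    if n_translocations < 0 or n_inversions < 0:
        raise ValueError("move counts must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(order.genes)
    log: list[dict] = []
    n = len(genes)
    for _ in range(n_translocations):
        src = int(rng.integers(n))
        dst = int(rng.integers(n - 1))
        log.append({"move": "translocation", "src": src, "dst": dst})
        gene = genes.pop(src)
        genes.insert(dst, gene)
    for _ in range(n_inversions):
        start = int(rng.integers(n))
        length = int(rng.integers(2, n))  # proper segment, not whole circle
        log.append({"move": "inversion", "start": start, "length": length})
        genes = _apply_inversion(genes, start, length)
    return SignedGeneOrder(tuple(genes)), log


def _apply_inversion(
    genes: list[Signed], start: int, length: int
) -> list[Signed]:
    n = len(genes)
    idx = [(start + k) % n for k in range(length)]
    segment = [genes[i] for i in idx]
    flipped = [(g, -s) for g, s in reversed(segment)]
    out = genes[:]
    for i, gs in zip(idx, flipped):
        out[i] = gs
    return out


def replay_moves(
    order: SignedGeneOrder, log: Sequence[Mapping]
) -> SignedGeneOrder:
    """Re-apply a move log; reproduces perturb_order's output exactly."""
    genes = list(order.genes)
    for move in log:
        if move["move"] == "translocation":
            gene = genes.pop(move["src"])
            genes.insert(move["dst"], gene)
        elif move["move"] == "inversion":
            genes = _apply_inversion(genes, move["start"], move["length"])
        else:
            raise ValueError(f"unknown move {move['move']!r}")
    return SignedGeneOrder(tuple(genes))
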