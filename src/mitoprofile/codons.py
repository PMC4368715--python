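"""CDS extraction, translation under the invertebrate mitochondrial code,
and codon / start-codon / stop-codon censuses.

The genetic code is NCBI translation table 5 (invertebrate mitochondrial):
relative to the standard code, ATA encodes Met, TGA encodes Trp and AGA/AGG
encode Ser; the only stop codons are TAA and TAG.  Codon-usage tables here
*include* initiation and termination codons — many codon-usage tools exclude
stops, but the published census this package mirrors counts them (its TAA/TAG
rows equal the number of protein-coding genes).
"""

from __future__ import annotations

import io as _io
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from .annotation import CircularAnnotation, GeneFeature
from .composition import extract_region
from .errors import AnnotationParseError, SequenceError

BASES = "TCAG"
ALL_CODONS = tuple(
    "".join(p) for p in product("ACGT", repeat=3)
)  # lexicographic
STOP = "*"


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid mapping plus permitted initiation codons."""

    table_id: int
    mapping: dict[str, str]  # 64 codons -> one-letter aa or "*"
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.mapping) != set(ALL_CODONS):
            raise ValueError("genetic code must map exactly the 64 codons")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.mapping.items() if aa == STOP)

    def translate_codon(self, codon: str) -> str:
        return self.mapping[codon.upper()]


def invertebrate_mito_code() -> GeneticCode:
    """NCBI transl_table 5, built from Biopython's codon tables."""
    table = CodonTable.unambiguous_dna_by_id[5]
    mapping = {c: table.forward_table[c] for c in table.forward_table}
    for c in table.stop_codons:
        mapping[c] = STOP
    mapping = {c.upper(): aa for c, aa in mapping.items()}
    return GeneticCode(
        table_id=5,
        mapping=mapping,
        start_codons=frozenset(c.upper() for c in table.start_codons),
    )


@dataclass(frozen=True)
class CdsCodons:
    """A CDS as consecutive 3-mers; a trailing 1-2 nt remainder is flagged."""

    gene: str
    codons: tuple[str, ...]
    remainder: str = ""

    def __len__(self) -> int:
        return len(self.codons)


def extract_cds(seq: str, f: GeneFeature) -> CdsCodons:
    """Extract the coding sequence of a protein-coding feature as codons.

    The plus-strand slice [start, end] is taken and reverse complemented for
    minus-strand genes.  A trailing remainder of 1-2 nt is returned in
    ``remainder`` rather than silently dropped.
    """
    if f.category != "PCG":
        raise SequenceError(f"{f.name}: extract_cds requires a PCG feature")
    cds = extract_region(
        seq, f.start, f.end, strand=f.strand, wrap=f.spans_origin
    )
    if len(cds) < 3:
        raise SequenceError(f"{f.name}: CDS shorter than one codon")
    n_full = len(cds) // 3
    codons = tuple(cds[3 * i : 3 * i + 3] for i in range(n_full))
    return CdsCodons(f.name, codons, cds[3 * n_full :])


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    internal_stop_indices: tuple[int, ...]  # 0-based codon indices, excl. final


def translate(
    codons: Sequence[str] | CdsCodons,
    code: GeneticCode | None = None,
    on_ambiguous: str = "X",
) -> TranslationResult:
    """Translate codons; internal stops are reported with their indices.

    Codons containing N (or other ambiguity) translate to ``on_ambiguous``
    ("X" by default) or raise when ``on_ambiguous='error'``.
    """
    if code is None:
        code = invertebrate_mito_code()
    if isinstance(codons, CdsCodons):
        codons = codons.codons
    out = []
    stops = []
    last = len(codons) - 1
    for i, codon in enumerate(codons):
        codon = codon.upper()
        if codon in code.mapping:
            aa = code.mapping[codon]
        elif on_ambiguous == "error":
            raise SequenceError(f"ambiguous codon {codon!r} at index {i}")
        else:
            aa = on_ambiguous
        if aa == STOP and i != last:
            stops.append(i)
        out.append(aa)
    return TranslationResult("".join(out), tuple(stops))


@dataclass(frozen=True)
class CodonUsageTable:
    """64 codon counts with their amino-acid mapping (stops included)."""

    counts: dict[str, int]
    code: GeneticCode = field(compare=False)
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        full = {c: int(self.counts.get(c, 0)) for c in ALL_CODONS}
        if any(v < 0 for v in full.values()):
            raise ValueError("codon counts must be non-negative")
        object.__setattr__(self, "counts", full)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def amino_acid(self, codon: str) -> str:
        return self.code.mapping[codon.upper()]


def codon_census(
    ann: CircularAnnotation, seq: str, code: GeneticCode | None = None
) -> CodonUsageTable:
    """Total codon usage across all protein-coding genes, stops included.

    Each gene contributes every complete codon of its CDS (start and stop
    codons included); nucleotides shared by overlapping genes are counted
    once per gene they belong to.  Genes whose span is not a multiple of 3
    contribute their complete codons and attach a warning.
    """
    if code is None:
        code = invertebrate_mito_code()
    if len(seq) != ann.genome_length:
        raise SequenceError(
            f"sequence length {len(seq)} != genome_length {ann.genome_length}"
        )
    pcgs = ann.by_category("PCG")
    if not pcgs:
        raise AnnotationParseError("annotation contains no protein-coding gene")
    counts: Counter[str] = Counter()
    warnings = []
    for f in pcgs:
        cds = extract_cds(seq, f)
        if cds.remainder:
            warnings.append(
                f"{f.name}: {len(cds.remainder)} nt trailing remainder "
                "excluded from the census"
            )
        counts.update(c for c in cds.codons if set(c) <= set("ACGT"))
    return CodonUsageTable(dict(counts), code, tuple(warnings))


@dataclass(frozen=True)
class CodonCensus:
    """Start-codon and stop-codon tallies over the protein-coding genes."""

    starts: dict[str, int]
    stops: dict[str, int]
    per_gene: tuple[tuple[str, str | None, str | None], ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def n_genes(self) -> int:
        return sum(self.starts.values())


def start_stop_census(
    ann: CircularAnnotation,
    seq: str | None = None,
    code: GeneticCode | None = None,
) -> CodonCensus:
    """Tally initiation and termination codons across the PCGs.

    With a sequence, the first and last codon of each CDS are read from it;
    without one, the table's printed start/stop codon columns are tallied.
    Genes lacking both are excluded with a warning.
    """
    if code is None:
        code = invertebrate_mito_code()
    starts: Counter[str] = Counter()
    stops: Counter[str] = Counter()
    per_gene = []
    warnings = []
    for f in ann.by_category("PCG"):
        first = last = None
        if seq is not None:
            cds = extract_cds(seq, f)
            first, last = cds.codons[0], cds.codons[-1]
        elif f.printed_start_codon or f.printed_stop_codon:
            first, last = f.printed_start_codon, f.printed_stop_codon
        if first is None and last is None:
            warnings.append(
                f"{f.name}: no sequence and no printed codons; excluded"
            )
            continue
        if first:
            starts[first.upper()] += 1
        if last:
            stops[last.upper()] += 1
        per_gene.append((f.name, first, last))
    return CodonCensus(
        dict(starts), dict(stops), tuple(per_gene), tuple(warnings)
    )


def rank_codons(
    table: CodonUsageTable, k: int = 64
) -> list[tuple[str, int]]:
    """Top-``k`` codons by count, descending; ties broken lexicographically."""
    if k > 64:
        raise ValueError("k must be <= 64")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


# ---------------------------------------------------------------------------
# Table layout IO (codon, amino acid, frequency; 64 rows)
# ---------------------------------------------------------------------------


def read_codon_table(
    text: str, code: GeneticCode | None = None
) -> CodonUsageTable:
    """Read a 64-row codon/aa/frequency table (tab separated, # comments).

    The amino-acid column is checked against the genetic code; a mismatch
    raises, since it indicates the table was built under a different code.
    """
    if code is None:
        code = invertebrate_mito_code()
    counts: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if cells[0].lower() in {"codon"}:
            continue
        if len(cells) < 3:
            raise AnnotationParseError("expected codon<TAB>aa<TAB>count", lineno)
        codon, aa, freq = cells[0].upper(), cells[1].strip(), cells[2]
        if codon not in code.mapping:
            raise AnnotationParseError(f"unknown codon {codon!r}", lineno)
        expected = code.mapping[codon]
        if aa.upper() not in {expected, "STOP" if expected == STOP else expected}:
            if not (aa == STOP and expected == STOP):
                raise AnnotationParseError(
                    f"{codon}: amino acid {aa!r} does not match "
                    f"table-{code.table_id} translation {expected!r}",
                    lineno,
                )
        if codon in counts:
            raise AnnotationParseError(f"duplicate codon {codon}", lineno)
        counts[codon] = int(freq)
    if len(counts) != 64:
        raise AnnotationParseError(
            f"expected 64 codon rows, found {len(counts)}"
        )
    return CodonUsageTable(counts, code)


def write_codon_table(table: CodonUsageTable) -> str:
    out = _io.StringIO()
    out.write("codon\taa\tfrequency\n")
    for codon in ALL_CODONS:
        out.write(
            f"{codon}\t{table.amino_acid(codon)}\t{table.counts[codon]}\n"
        )
    return out.getvalue()


def load_bundled_codon_table() -> CodonUsageTable:
    """The bundled S. maritima total codon-usage census (3,671 codons)."""
    text = (
        resources.files("mitoprofile.data")
        .joinpath("strigamia_codon_usage.tsv")
        .read_text()
    )
    return read_codon_table(text)
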