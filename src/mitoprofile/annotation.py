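"""Circular mitochondrial genome annotations and coordinate arithmetic.

Conventions (matching the published gene table this package profiles):

* coordinates are 1-based, both ends inclusive, always expressed on the
  plus strand;
* minus-strand features are recorded in ascending plus-strand coordinates
  (their sequence is the reverse complement of the plus-strand slice);
* the tabular dialect rejects origin-spanning features; the GFF3 reader
  accepts them as two-part joins and marks them ``spans_origin``.

Printed metadata columns (length, start/stop codon, intergenic spacer) are
retained verbatim and never override coordinates; ``validate_annotation``
surfaces any disagreement as warnings.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Sequence

from .errors import (
    AnnotationParseError,
    CoordinateError,
    RangeError,
)

CATEGORIES = ("PCG", "rRNA", "tRNA", "NC")

#: Columns of the tabular annotation dialect, in canonical order.
TABLE_COLUMNS = (
    "gene",
    "strand",
    "start",
    "end",
    "length",
    "start_codon",
    "stop_codon",
    "intergenic",
)

_MISSING = {"", ".", "na", "none"}


def infer_category(name: str) -> str:
    """Infer a feature category from its label prefix.

    ``trn*`` -> tRNA, ``rrn*`` -> rRNA, ``NC*`` -> NC, anything else -> PCG.
    The published table carries no category column, so this prefix rule is
    the default; an explicit ``category`` column overrides it.
    """
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    if name.upper().startswith("NC"):
        return "NC"
    return "PCG"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the circular molecule.

    ``printed_*`` fields reproduce the source table verbatim (advisory only);
    coordinates are authoritative.
    """

    name: str
    category: str
    strand: str  # "+", "-" or "." (unstranded, NC regions)
    start: int
    end: int
    printed_length: int | None = None
    printed_start_codon: str | None = None
    printed_stop_codon: str | None = None
    printed_intergenic: int | None = None
    spans_origin: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CoordinateError(
                f"{self.name}: unknown category {self.category!r}"
            )
        if self.strand not in {"+", "-", "."}:
            raise CoordinateError(f"{self.name}: bad strand {self.strand!r}")
        if self.category == "PCG" and self.strand not in {"+", "-"}:
            raise CoordinateError(
                f"{self.name}: protein-coding features must be stranded"
            )
        if self.start < 1 or self.end < 1:
            raise RangeError(f"{self.name}: coordinates must be >= 1")
        if self.spans_origin:
            if self.start <= self.end:
                raise CoordinateError(
                    f"{self.name}: origin-spanning feature requires start > end"
                )
        elif self.start > self.end:
            raise CoordinateError(
                f"{self.name}: start {self.start} > end {self.end}"
            )

    @property
    def is_coding(self) -> bool:
        """True for PCG/rRNA/tRNA (the categories counted as coding DNA)."""
        return self.category != "NC"


def feature_length(f: GeneFeature, genome_length: int | None = None) -> int:
    """Length of a feature in nucleotides (both ends inclusive).

    Origin-spanning features need ``genome_length`` to resolve the wrap.
    """
    if not f.spans_origin:
        return f.end - f.start + 1
    if genome_length is None:
        raise RangeError(
            f"{f.name}: genome length required for an origin-spanning feature"
        )
    return (genome_length - f.start + 1) + f.end


def feature_intervals(
    f: GeneFeature, genome_length: int
) -> list[tuple[int, int]]:
    """Decompose a feature into 1..genome_length linear interval(s)."""
    if f.end > genome_length or f.start > genome_length:
        raise RangeError(
            f"{f.name}: [{f.start},{f.end}] outside genome of "
            f"length {genome_length}"
        )
    if f.spans_origin:
        return [(f.start, genome_length), (1, f.end)]
    return [(f.start, f.end)]


@dataclass(frozen=True)
class CircularAnnotation:
    """An ordered feature list on a circle of known length."""

    genome_length: int
    features: tuple[GeneFeature, ...]
    source_notes: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise RangeError("genome_length must be positive")
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationParseError(
                f"duplicate feature names: {sorted(dupes)}"
            )
        for f in self.features:
            if max(f.start, f.end) > self.genome_length:
                raise RangeError(
                    f"{f.name}: [{f.start},{f.end}] outside genome of "
                    f"length {self.genome_length}"
                )
        ordered = tuple(
            sorted(self.features, key=lambda f: (f.start, f.end, f.name))
        )
        object.__setattr__(self, "features", ordered)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_category(self, category: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.category == category)

    def consecutive_pairs(self) -> list[tuple[GeneFeature, GeneFeature]]:
        """All (prev, next) pairs in annotation order, including the wrap pair."""
        fs = self.features
        if len(fs) < 2:
            return []
        pairs = list(zip(fs, fs[1:]))
        pairs.append((fs[-1], fs[0]))
        return pairs


def intergenic_value(
    prev: GeneFeature, next_: GeneFeature, genome_length: int,
    wrap: bool | None = None,
) -> int:
    """Signed spacer between consecutive features.

    Positive = gap length, negative = overlap length, 0 = abutting.
    The wrap pair (last feature -> first feature) measures the spacer across
    the origin of the circle; by default it is inferred from the coordinates
    (next_ starting before prev, or a feature paired with itself), and
    callers that know the pair's position can pass ``wrap`` explicitly.
    """
    if genome_length < prev.end:
        raise RangeError(
            f"genome length {genome_length} < end of {prev.name} ({prev.end})"
        )
    if wrap is None:
        wrap = prev is next_ or next_.start < prev.start
    if wrap:
        # next_ restarts the circle (a single feature pairs with itself and
        # the spacer is the rest of the circle)
        return genome_length - prev.end + next_.start - 1
    return next_.start - prev.end - 1


@dataclass(frozen=True)
class ValidationWarning:
    feature: str
    field: str
    printed: object
    recomputed: object
    message: str


@dataclass(frozen=True)
class ValidationReport:
    """Disagreements between printed metadata and coordinate arithmetic."""

    warnings: tuple[ValidationWarning, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.warnings

    def for_feature(self, name: str) -> tuple[ValidationWarning, ...]:
        return tuple(w for w in self.warnings if w.feature == name)

    def __len__(self) -> int:
        return len(self.warnings)


def validate_annotation(ann: CircularAnnotation) -> ValidationReport:
    """Recompute lengths and intergenic spacers; report printed-value mismatches.

    Coordinates are authoritative and the annotation is never mutated; every
    finding is a warning, not an error, because published tables are known to
    carry internal contradictions.
    """
    warnings: list[ValidationWarning] = []
    for f in ann:
        if f.printed_length is not None:
            span = feature_length(f, ann.genome_length)
            if span != f.printed_length:
                warnings.append(
                    ValidationWarning(
                        f.name,
                        "length",
                        f.printed_length,
                        span,
                        f"{f.name}: printed length {f.printed_length} != "
                        f"coordinate span {span}",
                    )
                )
    pairs = ann.consecutive_pairs()
    for i, (prev, next_) in enumerate(pairs):
        if next_.printed_intergenic is None:
            continue
        got = intergenic_value(
            prev, next_, ann.genome_length, wrap=(i == len(pairs) - 1)
        )
        if got != next_.printed_intergenic:
            warnings.append(
                ValidationWarning(
                    next_.name,
                    "intergenic",
                    next_.printed_intergenic,
                    got,
                    f"{prev.name}->{next_.name}: printed intergenic "
                    f"{next_.printed_intergenic:+d} != recomputed {got:+d}",
                )
            )
    return ValidationReport(tuple(warnings))


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

_HEADER_ALIASES = {
    "gene": "gene",
    "name": "gene",
    "feature": "gene",
    "strand": "strand",
    "start": "start",
    "start_position": "start",
    "end": "end",
    "end_position": "end",
    "length": "length",
    "start_codon": "start_codon",
    "stop_codon": "stop_codon",
    "intergenic": "intergenic",
    "intergenic_nucleotides": "intergenic",
    "category": "category",
}


def _normalise_header(cell: str) -> str | None:
    key = re.sub(r"[^a-z0-9]+", "_", cell.strip().lower()).strip("_")
    return _HEADER_ALIASES.get(key)


def _parse_int(cell: str, what: str, line: int) -> int:
    try:
        return int(cell.replace("+", "", 1)) if cell.startswith("+") else int(cell)
    except ValueError:
        raise AnnotationParseError(f"bad {what} value {cell!r}", line) from None


def parse_annotation(
    table_text: str, genome_length: int, source_notes: str = ""
) -> CircularAnnotation:
    """Parse the tabular annotation dialect into a :class:`CircularAnnotation`.

    The dialect is a delimited table (tab or comma), ``#`` comment lines
    ignored, with a header naming at least gene/strand/start/end; length,
    start_codon, stop_codon, intergenic and category columns are optional in
    any subset.  ``.`` or an empty cell marks a missing value.
    """
    lines = table_text.splitlines()
    header: dict[int, str] | None = None
    sep = "\t"
    features: list[GeneFeature] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if header is None:
            sep = "\t" if "\t" in line else ","
            cells = [c for c in line.split(sep)]
            header = {}
            for i, cell in enumerate(cells):
                canon = _normalise_header(cell)
                if canon is not None:
                    header[i] = canon
            required = {"gene", "strand", "start", "end"}
            if not required.issubset(set(header.values())):
                missing = required - set(header.values())
                raise AnnotationParseError(
                    f"header lacks required column(s) {sorted(missing)}", lineno
                )
            continue
        cells = line.split(sep)
        row = {
            header[i]: cells[i].strip()
            for i in header
            if i < len(cells)
        }
        for col in ("gene", "strand", "start", "end"):
            if col not in row or row[col] == "":
                raise AnnotationParseError(
                    f"malformed row (missing {col!r}): {line!r}", lineno
                )
        name = row["gene"].strip("*")
        strand = row["strand"] if row["strand"] not in _MISSING else "."
        start = _parse_int(row["start"], "start", lineno)
        end = _parse_int(row["end"], "end", lineno)
        if start > end:
            raise CoordinateError(
                f"line {lineno}: {name}: start {start} > end {end} "
                "(origin-spanning features are not representable in the "
                "tabular dialect)"
            )
        if not (1 <= start <= genome_length and 1 <= end <= genome_length):
            raise RangeError(
                f"line {lineno}: {name}: [{start},{end}] outside "
                f"[1,{genome_length}]"
            )
        category = row.get("category", "")
        category = category if category not in _MISSING else infer_category(name)

        def _opt_int(col: str) -> int | None:
            v = row.get(col, "")
            return None if v in _MISSING else _parse_int(v, col, lineno)

        def _opt_str(col: str) -> str | None:
            v = row.get(col, "")
            return None if v in _MISSING else v.upper()

        features.append(
            GeneFeature(
                name=name,
                category=category,
                strand=strand,
                start=start,
                end=end,
                printed_length=_opt_int("length"),
                printed_start_codon=_opt_str("start_codon"),
                printed_stop_codon=_opt_str("stop_codon"),
                printed_intergenic=_opt_int("intergenic"),
            )
        )
    if header is None:
        raise AnnotationParseError("no header row found")
    return CircularAnnotation(
        genome_length=genome_length,
        features=tuple(features),
        source_notes=source_notes,
    )


def write_annotation(ann: CircularAnnotation) -> str:
    """Serialise to the tabular dialect; ``parse_annotation`` round-trips it."""
    out = io.StringIO()
    out.write(
        "# Circular annotation, coordinates 1-based both-ends-inclusive "
        f"(genome length {ann.genome_length} nt).\n"
    )
    out.write("\t".join(TABLE_COLUMNS) + "\tcategory\n")
    for f in ann:
        cells = [
            f.name,
            f.strand,
            str(f.start),
            str(f.end),
            "." if f.printed_length is None else str(f.printed_length),
            f.printed_start_codon or ".",
            f.printed_stop_codon or ".",
            "."
            if f.printed_intergenic is None
            else format(f.printed_intergenic, "+d")
            if f.printed_intergenic
            else "0",
            f.category,
        ]
        out.write("\t".join(cells) + "\n")
    return out.getvalue()


def rotate_annotation(ann: CircularAnnotation, k: int) -> CircularAnnotation:
    """Rotate all coordinates by ``k`` positions around the circle.

    Raises :class:`CoordinateError` if the rotation would split a feature
    across the origin (the tabular dialect cannot represent that).
    """
    L = ann.genome_length
    rotated = []
    for f in ann:
        ns = (f.start - 1 + k) % L + 1
        ne = (f.end - 1 + k) % L + 1
        if ns > ne:
            raise CoordinateError(
                f"rotation by {k} splits {f.name} across the origin"
            )
        rotated.append(replace(f, start=ns, end=ne, printed_intergenic=None))
    return CircularAnnotation(L, tuple(rotated), ann.source_notes)


def load_bundled_annotation() -> CircularAnnotation:
    """The bundled Strigamia maritima mitochondrial gene table (14,983 bp)."""
    text = (
        resources.files("mitoprofile.data")
        .joinpath("strigamia_mt_features.tsv")
        .read_text()
    )
    return parse_annotation(
        text, genome_length=14983, source_notes="bundled S. maritima gene table"
    )
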