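"""Readers and writers for standard genome formats.

The in-memory annotation container is :class:`~mitoprofile.annotation.
CircularAnnotation` (1-based, both-ends-inclusive, plus-strand coordinates).
Conversions to other conventions (BED's 0-based half-open, GFF3 joins) are
handled here and never leak into the rest of the package.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import (
    CircularAnnotation,
    GeneFeature,
    feature_intervals,
    infer_category,
)
from .errors import AnnotationParseError, SequenceError

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (id, sequence).

    Raises :class:`SequenceError` for empty, multi-record or non-ACGTN input.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA record found")
    if len(records) > 1:
        raise SequenceError(
            f"{path}: expected a single record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise SequenceError(f"{path}: empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceError(f"{path}: non-ACGTN characters {sorted(bad)}")
    return rec.id, seq


def write_fasta(path: str | Path, name: str, seq: str, width: int = 70) -> None:
    rec = SeqRecord(Seq(seq), id=name, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    _ = width  # Biopython wraps at 60; width retained for API stability


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_TYPE_BY_CATEGORY = {
    "PCG": "gene",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "NC": "misc_feature",
}
_CATEGORY_BY_GFF_TYPE = {
    "gene": "PCG",
    "cds": "PCG",
    "mrna": "PCG",
    "rrna": "rRNA",
    "trna": "tRNA",
    "misc_feature": "NC",
    "region": "NC",
}


def write_gff3(ann: CircularAnnotation, seqid: str = "genome") -> str:
    out = _io.StringIO()
    out.write("##gff-version 3\n")
    out.write(f"##sequence-region {seqid} 1 {ann.genome_length}\n")
    for f in ann:
        strand = f.strand if f.strand in {"+", "-"} else "."
        for part, (s, e) in enumerate(
            feature_intervals(f, ann.genome_length), start=1
        ):
            attrs = f"ID={f.name};Name={f.name};category={f.category}"
            if f.spans_origin:
                attrs += f";part={part}"
            out.write(
                "\t".join(
                    [
                        seqid,
                        "mitoprofile",
                        _GFF_TYPE_BY_CATEGORY[f.category],
                        str(s),
                        str(e),
                        ".",
                        strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
    return out.getvalue()


def _gff_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise AnnotationParseError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(text: str, genome_length: int | None = None) -> CircularAnnotation:
    """Parse GFF3 into a circular annotation.

    Two lines sharing an ID are interpreted as a two-part join of an
    origin-spanning feature (first part must run to the genome end, second
    must start at 1).  ``##sequence-region`` supplies the genome length
    unless given explicitly.
    """
    rows: dict[str, list[tuple[str, int, int, str]]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                genome_length = int(parts[3])
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationParseError(
                f"expected 9 tab-separated columns, got {len(cols)}", lineno
            )
        _, _, ftype, start, end, _, strand, _, attr_field = cols
        attrs = _gff_attributes(attr_field)
        name = attrs.get("ID") or attrs.get("Name")
        if not name:
            raise AnnotationParseError("feature lacks ID/Name", lineno)
        category = attrs.get("category") or _CATEGORY_BY_GFF_TYPE.get(
            ftype.lower()
        )
        if category is None:
            category = infer_category(name)
        if name not in rows:
            order.append(name)
        rows.setdefault(name, []).append(
            (category, int(start), int(end), strand)
        )
    if genome_length is None:
        raise AnnotationParseError(
            "genome length unknown: no ##sequence-region directive and no "
            "explicit genome_length"
        )
    features = []
    for name in order:
        parts = sorted(rows[name], key=lambda r: r[1])
        category, start, end, strand = parts[0]
        if len(parts) == 1:
            features.append(
                GeneFeature(name, category, strand, start, end)
            )
        elif len(parts) == 2:
            (c1, s1, e1, st1), (c2, s2, e2, st2) = parts
            if s1 != 1 or e2 != genome_length or st1 != st2:
                raise AnnotationParseError(
                    f"{name}: two-part join must be [x,{genome_length}] + "
                    f"[1,y] on one strand"
                )
            features.append(
                GeneFeature(
                    name, c1, st1, start=s2, end=e1, spans_origin=True
                )
            )
        else:
            raise AnnotationParseError(
                f"{name}: more than two parts are not supported"
            )
    return CircularAnnotation(genome_length, tuple(features), "from GFF3")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(ann: CircularAnnotation, seqid: str = "genome") -> str:
    """BED6; conversion to 0-based half-open happens here only."""
    out = _io.StringIO()
    for f in ann:
        strand = f.strand if f.strand in {"+", "-"} else "."
        for s, e in feature_intervals(f, ann.genome_length):
            out.write(
                "\t".join(
                    [seqid, str(s - 1), str(e), f.name, "0", strand]
                )
                + "\n"
            )
    return out.getvalue()


# ---------------------------------------------------------------------------
# GenBank flat file (feature table only)
# ---------------------------------------------------------------------------

_GB_TYPES = {"gene", "CDS", "tRNA", "rRNA", "misc_feature", "D-loop"}


def read_genbank(path_or_handle) -> tuple[CircularAnnotation, str | None]:
    """Minimal GenBank reader: feature table -> annotation, plus sequence.

    CDS/gene features map to PCG, tRNA/rRNA to their categories,
    misc_feature/D-loop to NC.  Compound (join) locations crossing the
    origin become ``spans_origin`` features.  Returns (annotation,
    sequence-or-None).
    """
    record = SeqIO.read(path_or_handle, "genbank")
    L = len(record.seq)
    seq = str(record.seq).upper() if len(record.seq) else None
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type not in _GB_TYPES:
            continue
        quals = feat.qualifiers
        name = (
            quals.get("gene", [None])[0]
            or quals.get("product", [None])[0]
            or quals.get("note", [None])[0]
        )
        if not name:
            continue
        name = re.sub(r"\s+", "_", name.strip())
        if name in seen:  # gene + CDS pairs describe the same feature
            continue
        seen.add(name)
        if feat.type in {"tRNA", "rRNA"}:
            category = feat.type
        elif feat.type in {"misc_feature", "D-loop"}:
            category = "NC"
        else:
            category = infer_category(name)
        strand = {1: "+", -1: "-", None: "."}.get(feat.location.strand, ".")
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        if len(parts) == 1:
            start = int(parts[0].start) + 1
            end = int(parts[0].end)
            features.append(GeneFeature(name, category, strand, start, end))
        else:
            first, last = parts[0], parts[-1]
            if int(first.start) == 0 and int(last.end) == L:
                features.append(
                    GeneFeature(
                        name,
                        category,
                        strand,
                        start=int(last.start) + 1,
                        end=int(first.end),
                        spans_origin=True,
                    )
                )
            else:
                raise AnnotationParseError(
                    f"{name}: unsupported compound location"
                )
    ann = CircularAnnotation(L, tuple(features), f"from GenBank {record.id}")
    return ann, seq
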