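"""Pipeline assembly: one profiling run over a genome + annotation.

``run_profile`` executes composition -> codon machinery -> non-coding scan
-> gene order in sequence and collects everything into a
:class:`ProfileReport`; every number in the report is recomputed from the
inputs within the same run.  An annotation-only mode (no FASTA) restricts
the report to coordinate-derived statistics and printed-column censuses,
marking sequence-dependent sections as absent rather than degrading
silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation as _ann
from . import codons as _codons
from . import composition as _comp
from . import geneorder as _go
from . import io as _io
from . import noncoding as _nc
from .errors import MitoprofileError, SequenceError


@dataclass
class ProfileReport:
    genome_length: int
    sequence_available: bool
    composition: _comp.CompositionProfile | None
    validation: _ann.ValidationReport
    feature_table: pd.DataFrame
    codon_table: _codons.CodonUsageTable | None
    census: _codons.CodonCensus
    coverage_union: _nc.CoverageBreakdown
    coverage_overlap: _nc.CoverageBreakdown
    noncoding: list
    control_regions: list
    order_comparison: _go.OrderComparison | None
    notes: list[str] = field(default_factory=list)

    def summary_lines(self) -> list[str]:
        lines = [
            f"genome length: {self.genome_length} nt "
            f"({'sequence + annotation' if self.sequence_available else 'annotation only'})"
        ]
        if self.composition is not None:
            c = self.composition
            lines.append(
                "plus-strand composition: "
                f"A={c.fraction('a'):.2f}% C={c.fraction('c'):.2f}% "
                f"G={c.fraction('g'):.2f}% T={c.fraction('t'):.2f}%"
            )
            lines.append(
                f"A+T content: {c.at_content:.2f}%  "
                f"AT-skew: {c.at_skew:+.2f}  GC-skew: {c.gc_skew:+.2f}"
            )
        lines.append(
            f"coding DNA (union rule): {self.coverage_union.coding_fraction:.2f}% "
            f"of the genome; bases under >=2 features: "
            f"{self.coverage_union.overlap_bases} nt"
        )
        starts = ", ".join(
            f"{c}x{n}" for c, n in sorted(self.census.starts.items())
        )
        stops = ", ".join(
            f"{c}x{n}" for c, n in sorted(self.census.stops.items())
        )
        lines.append(f"start codons: {starts}")
        lines.append(f"stop codons: {stops}")
        lines.append(
            f"non-coding regions: {len(self.noncoding)}; proposed control "
            f"regions: {len(self.control_regions)}"
        )
        if self.validation.warnings:
            lines.append(
                f"annotation warnings: {len(self.validation.warnings)} "
                "(printed columns vs coordinates)"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return lines


def _feature_dataframe(
    ann: _ann.CircularAnnotation, seq: str | None
) -> pd.DataFrame:
    rows = []
    all_pairs = ann.consecutive_pairs()
    pairs = {
        b.name: _ann.intergenic_value(
            a, b, ann.genome_length, wrap=(i == len(all_pairs) - 1)
        )
        for i, (a, b) in enumerate(all_pairs)
    }
    for f in ann:
        row = {
            "gene": f.name,
            "category": f.category,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "length": _ann.feature_length(f, ann.genome_length),
            "printed_length": f.printed_length,
            "intergenic": pairs.get(f.name),
            "printed_intergenic": f.printed_intergenic,
        }
        if seq is not None:
            prof = _comp.region_composition(seq, f)
            row["at_content_pct"] = round(prof.at_content, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def run_profile(
    genome: str | Path | None,
    annotation: str | Path,
    genome_length: int | None = None,
    reference_order: _go.SignedGeneOrder | None = None,
    alpha: float = 0.01,
    min_len: int = 200,
    variant: str = "gof",
    out_dir: str | Path | None = None,
) -> ProfileReport:
    """Profile a genome (or an annotation alone) and optionally write files.

    ``genome`` is a single-record FASTA path or None for annotation-only
    mode.  ``annotation`` is a tabular-dialect path; ``genome_length`` is
    required only when no FASTA is given and defaults to the sequence
    length otherwise.  A fatal mismatch between FASTA length and the stated
    genome length raises with both lengths in the message.
    """
    seq = None
    if genome is not None:
        _, seq = _io.read_fasta(genome)
        if genome_length is not None and genome_length != len(seq):
            raise SequenceError(
                f"annotation genome length {genome_length} != FASTA length "
                f"{len(seq)}"
            )
        genome_length = len(seq)
    if genome_length is None:
        raise MitoprofileError(
            "genome_length is required in annotation-only mode"
        )
    ann = _ann.parse_annotation(
        Path(annotation).read_text(), genome_length=genome_length
    )

    notes = []
    composition = _comp.base_composition(seq) if seq else None
    validation = _ann.validate_annotation(ann)
    feature_table = _feature_dataframe(ann, seq)

    codon_table = None
    if seq is not None and ann.by_category("PCG"):
        codon_table = _codons.codon_census(ann, seq)
    elif seq is None:
        notes.append("no sequence: codon-usage table absent")

    census = _codons.start_stop_census(ann, seq)
    if seq is None:
        notes.append("censuses tallied from printed start/stop columns")

    coverage_union = _nc.coverage_breakdown(ann, "union")
    coverage_overlap = _nc.coverage_breakdown(ann, "per-category-with-overlap")
    noncoding = _nc.enumerate_noncoding(ann)
    if seq is not None:
        control = _nc.propose_control_regions(
            ann, seq, alpha=alpha, min_len=min_len, variant=variant
        )
    else:
        control = []
        notes.append("no sequence: AT-enrichment tests absent")

    comparison = None
    if reference_order is not None:
        comparison = _go.compare_orders(
            _go.to_signed_order(ann), reference_order, max_gap=1
        )

    report = ProfileReport(
        genome_length=genome_length,
        sequence_available=seq is not None,
        composition=composition,
        validation=validation,
        feature_table=feature_table,
        codon_table=codon_table,
        census=census,
        coverage_union=coverage_union,
        coverage_overlap=coverage_overlap,
        noncoding=noncoding,
        control_regions=control,
        order_comparison=comparison,
        notes=notes,
    )
    if out_dir is not None:
        write_report_files(report, ann, Path(out_dir))
    return report


def write_report_files(
    report: ProfileReport, ann: _ann.CircularAnnotation, out_dir: Path
) -> list[Path]:
    """Write TSV/JSON/BED/plain-text outputs; returns the paths written."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(name: str, text: str) -> None:
        p = out_dir / name
        p.write_text(text)
        written.append(p)

    # header comment naming the coordinate convention, '.' for missing
    table_text = report.feature_table.fillna(".").to_csv(
        sep="\t", index=False
    )
    emit(
        "features.tsv",
        "# coordinates 1-based, both ends inclusive, plus strand\n"
        + table_text,
    )
    if report.codon_table is not None:
        emit("codon_usage.tsv", _codons.write_codon_table(report.codon_table))
    emit(
        "censuses.json",
        json.dumps(
            {"starts": report.census.starts, "stops": report.census.stops},
            indent=1,
        ),
    )
    bed_lines = []
    tsv_lines = ["# start\tend\tlength\tsource\tname"]
    for r in report.noncoding:
        for s, e in r.intervals(report.genome_length):
            bed_lines.append(f"genome\t{s - 1}\t{e}\t{r.name or 'gap'}\t0\t.")
        tsv_lines.append(
            f"{r.start}\t{r.end}\t{r.length}\t{r.source}\t{r.name or '.'}"
        )
    emit("noncoding.bed", "\n".join(bed_lines) + "\n")
    emit("noncoding.tsv", "\n".join(tsv_lines) + "\n")
    control = [
        {
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "chi2": t.chi2,
            "pvalue": t.pvalue,
            "variant": t.variant,
        }
        for r, t in report.control_regions
    ]
    emit("control_regions.json", json.dumps(control, indent=1))
    if report.order_comparison is not None:
        emit("order_comparison.txt", _go.block_diagram(report.order_comparison))
    emit("report.txt", "\n".join(report.summary_lines()) + "\n")
    return written
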