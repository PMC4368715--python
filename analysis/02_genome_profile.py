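#!/usr/bin/env python
"""Profile the published gene table and the simulated stand-in genome.

Annotation-only pass over the published table (coordinate arithmetic,
printed-column censuses, validation warnings) and a full pass over the
simulated genome from step 01 (composition, skews, codon usage).  Tables go
to results/profile/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mitoprofile import (
    CompositionProfile,
    load_bundled_annotation,
    load_bundled_codon_table,
    rank_codons,
    run_profile,
    skews,
    start_stop_census,
    validate_annotation,
)
from mitoprofile.annotation import write_annotation

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    out = ROOT / "results" / "profile"
    out.mkdir(parents=True, exist_ok=True)

    # --- printed plus-strand composition -> skews -------------------------
    profile = CompositionProfile.from_fractions(
        a=38.96, c=23.90, g=12.08, t=25.06
    )
    at_skew, gc_skew = skews(profile)
    print("printed plus-strand fractions give "
          f"A+T {profile.at_content:.2f}%, AT-skew {at_skew:+.2f}, "
          f"GC-skew {gc_skew:+.2f}")

    # --- published table: censuses and internal consistency ---------------
    ann = load_bundled_annotation()
    census = start_stop_census(ann)
    starts = ", ".join(f"{c}x{n}" for c, n in sorted(census.starts.items()))
    stops = ", ".join(f"{c}x{n}" for c, n in sorted(census.stops.items()))
    print(f"printed start codons: {starts}; stop codons: {stops}")
    report = validate_annotation(ann)
    print(f"printed columns disagree with coordinates in "
          f"{len(report.warnings)} places:")
    for w in report.warnings:
        print(f"  {w.message}")
    pd.DataFrame(
        [w.__dict__ for w in report.warnings]
    ).to_csv(out / "validation_warnings.tsv", sep="\t", index=False)

    table = load_bundled_codon_table()
    top = rank_codons(table, 4)
    print("most frequent codons:",
          ", ".join(f"{c} (x{n})" for c, n in top))

    # --- full profile of the simulated genome -----------------------------
    sim = ROOT / "results" / "simulated"
    if not (sim / "genome.fasta").exists():
        print("note: run analysis/01_simulate_genome.py first for the "
              "sequence-dependent sections")
        return
    rep = run_profile(
        sim / "genome.fasta", sim / "features.tsv", out_dir=out / "simulated"
    )
    print("--- simulated genome ---")
    for line in rep.summary_lines():
        print(line)


if __name__ == "__main__":
    main()
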