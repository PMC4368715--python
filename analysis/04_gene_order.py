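#!/usr/bin/env python
"""Gene-order comparison against the arthropod ground plan.

Derives the signed circular gene order from the published table, compares
it with the Limulus polyphemus reference (breakpoints, conserved blocks at
gap tolerance 0 and 1, displaced genes) and writes results/gene_order/.
"""

import argparse
import json
from pathlib import Path

from mitoprofile import (
    conserved_blocks,
    ground_plan_order,
    load_bundled_annotation,
    to_signed_order,
)
from mitoprofile.geneorder import block_diagram, compare_orders

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    out = ROOT / "results" / "gene_order"
    out.mkdir(parents=True, exist_ok=True)

    order = to_signed_order(load_bundled_annotation()).anchored("cox1")
    reference = ground_plan_order()
    print("derived order:", order.to_string())

    comparison = compare_orders(order, reference)
    print(f"\ncommon genes: {len(comparison.common_labels)} "
          f"(reference-only: "
          f"{sorted(comparison.dropped_from_second)})")
    print(f"shared adjacencies: {comparison.shared_adjacencies}; "
          f"breakpoints: {comparison.breakpoints}")

    print("\nstrict conserved blocks (shared signed adjacencies):")
    for b in comparison.blocks:
        print("  " + " ".join(g if s > 0 else f"-{g}" for g, s in b.genes))
    print("blocks allowing one intervening translocated gene:")
    gapped = conserved_blocks(order, reference, max_gap=1)
    for b in gapped:
        print("  " + " ".join(g if s > 0 else f"-{g}" for g, s in b.genes))
    displaced = sorted(g for g, _ in comparison.displaced)
    print(f"\ngenes with no conserved flank ({len(displaced)}): "
          + " ".join(displaced))

    (out / "comparison.txt").write_text(block_diagram(comparison) + "\n")
    (out / "comparison.json").write_text(
        json.dumps(
            {
                "order": order.to_string(),
                "reference": reference.to_string(),
                "common_genes": len(comparison.common_labels),
                "shared_adjacencies": comparison.shared_adjacencies,
                "breakpoints": comparison.breakpoints,
                "blocks_strict": [list(b.labels) for b in comparison.blocks],
                "blocks_gap1": [list(b.labels) for b in gapped],
                "displaced": displaced,
            },
            indent=1,
        )
    )
    print(f"\nwrote {out}/comparison.txt and comparison.json")


if __name__ == "__main__":
    main()
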