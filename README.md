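# mitoprofile

Descriptive profiling of circular mitochondrial genomes, built around the
mitogenome of the geophilomorph centipede *Strigamia maritima* (14,983 bp;
13 protein-coding genes, 2 rRNAs, 16 identifiable tRNAs and two large
AT-rich non-coding regions). The package turns the descriptive analyses a
mitogenome announcement performs — gene accounting on the circle,
composition and strand-skew statistics, codon-usage and start/stop-codon
censuses, control-region detection by AT enrichment, and gene-order
comparison against the arthropod ground plan — into reusable, tested code
for anyone profiling a small circular genome from a feature table and
(optionally) its sequence.

## What it computes

* **Circular coordinate arithmetic** (`mitoprofile.annotation`): 1-based,
  both-ends-inclusive plus-strand coordinates; feature lengths; signed
  intergenic spacers (positive = gap, negative = overlap, wrap pair
  included); validation of printed table columns against the coordinates.
  Readers/writers for a tabular gene-table dialect, GFF3 (origin-spanning
  two-part joins supported), GenBank feature tables and BED.
* **Composition and skews** (`mitoprofile.composition`): per-base counts
  and percent fractions, A+T content, and the strand-asymmetry statistics
  AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), on whole genomes or
  regions (either strand, wrapping allowed).
* **Codon machinery** (`mitoprofile.codons`): CDS extraction on the
  circle, translation under the invertebrate mitochondrial code
  (transl_table 5: ATA→M, TGA→W, AGA/AGG→S; stops TAA/TAG only), codon-
  usage tables *including* stop codons, start/stop censuses from sequence
  or from printed table columns, and frequency ranking.
* **Non-coding scan** (`mitoprofile.noncoding`): exact enumeration of
  regions covered by no gene, coverage breakdowns under explicit
  overlap-attribution rules, and χ² AT-enrichment tests (goodness-of-fit
  and 2×2 contingency, with and without Yates correction) that propose
  AT-rich control regions.
* **Gene order** (`mitoprofile.geneorder`): signed circular permutations
  with rotation/reversal equivalence, head-tail adjacency breakpoint
  distance, maximal conserved blocks (optionally tolerating a bounded
  number of intervening translocated genes), displaced-gene detection, and
  a bundled *Limulus polyphemus* ground-plan reference order.
* **Synthetic genomes** (`mitoprofile.synthetic`): a seeded generator that
  emulates the real molecule — the full coordinate skeleton with its
  same-strand and opposite-strand overlaps, codon usage drawn from the
  published census, start codons ATT/ATG/ATA/ATC at 5/5/2/1, stops TAA/TAG
  at 8/5, AT-rich control regions on a 64% A+T background — plus
  gene-order perturbation with a replayable move log.

## Worked example

```python
>>> import mitoprofile as mp
>>> ann = mp.load_bundled_annotation()          # the published gene table
>>> mp.feature_length(ann.feature("nad5"))
1701
>>> mp.intergenic_value(ann.feature("cox3"), ann.feature("trnG"), 14983)
-54
>>> p = mp.CompositionProfile.from_fractions(a=38.96, c=23.90, g=12.08, t=25.06)
>>> round(p.at_content, 2), round(p.at_skew, 2), round(p.gc_skew, 2)
(64.02, 0.22, -0.33)
>>> census = mp.start_stop_census(ann)          # printed-column census
>>> census.starts
{'ATT': 5, 'ATG': 5, 'ATA': 2, 'ATC': 1}
>>> mp.rank_codons(mp.load_bundled_codon_table(), 2)
[('TTT', 226), ('ATT', 195)]
```

The nested tRNA-glycine gene sits entirely inside the cox3 reading frame
(spacer −54), the longest gene nad5 spans 1701 nt, and the strongly
A-skewed, C-over-G plus strand (AT-skew +0.22, GC-skew −0.33) is typical
of an asymmetrically replicating mitochondrial molecule.

The same numbers come from the command line:

```sh
mitoprofile validate src/mitoprofile/data/strigamia_mt_features.tsv --genome-length 14983
mitoprofile simulate --seed 1 --out-dir results/simulated
mitoprofile profile --genome results/simulated/genome.fasta \
    --annotation results/simulated/features.tsv
mitoprofile compare-order my_order.txt --max-gap 1
```

## Analysis scripts

The `analysis/` directory holds the narrative pipeline, each step a thin
driver over the library that prints what it found and writes tables under
`results/`:

1. `01_simulate_genome.py` — generate the seeded synthetic stand-in genome.
2. `02_genome_profile.py` — composition/skews from the printed fractions,
   printed-column censuses, table-vs-coordinate validation, full profile of
   the simulated genome.
3. `03_noncoding_regions.py` — non-coding region enumeration, coverage
   breakdowns under both overlap rules, and all four χ² variants on the two
   long non-coding regions.
4. `04_gene_order.py` — signed-order comparison against the arthropod
   ground plan: breakpoints, conserved blocks, displaced genes.

## Limitations

The package profiles *annotated* genomes: it performs no gene prediction,
tRNA detection or secondary-structure folding, no phylogenetic inference,
and no rearrangement-history reconstruction (gene-order comparison stops at
adjacencies, blocks and breakpoints). See `docs/methods.md` for the models,
conventions, and known discrepancies in the source tables.
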