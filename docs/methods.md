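# Methods

## Coordinate model

All annotations live on a circle of known length with 1-based,
both-ends-inclusive coordinates expressed on the plus strand — the strand
carrying the majority of protein-coding sequence, which is also the
reporting frame for composition. Minus-strand features are stored in
ascending plus-strand coordinates; their sequence is the reverse complement
of the slice. Internal conversions to 0-based half-open (BED) or to
two-part joins (GFF3, GenBank) happen in the I/O layer only.

The signed intergenic spacer between consecutive features is
`start(next) − end(prev) − 1`, with the wrap pair (last → first) measured
across the origin as `L − end(prev) + start(next) − 1`. Positive values
are gaps, negative values overlaps, zero means abutting. For any sorted
feature set, overlapping or not, the sum over consecutive pairs of
`length(next) + spacer(prev, next)` telescopes to the genome length; the
test suite asserts this as a property.

The bundled gene table is the published organisation of the *S. maritima*
molecule (33 features on 14,983 bp). Its printed length/spacer columns
disagree with its own coordinates in seven places (e.g. a printed length of
464 nt for a 465 nt span, a printed spacer of −23 where the coordinates
give −26). Coordinates are treated as authoritative; printed columns are
retained verbatim and every disagreement is surfaced as a validation
warning, never silently corrected. Two different total lengths appear in
the source material (14,938 and 14,983 bp); this package uses 14,983
throughout, the value consistent with the coordinates.

## Composition and skew statistics

Fractions are percentages of non-N positions; N is counted but excluded
from every denominator, and profiles record the N count so callers can
refuse high-ambiguity input. AT-skew = (A−T)/(A+T) and
GC-skew = (G−C)/(G+C) are scale-free, so they are computed identically
from counts or from printed percentages; a skew whose denominator is zero
raises rather than returning a silent 0. Reports round fractions and skews
to two decimals (the precision of the source tables) while full precision
is kept internally. A+T content of "the whole genome" is computed on the
plus strand; complementarity makes it strand-symmetric.

## Codon machinery

Translation uses NCBI table 5 (invertebrate mitochondrial) exactly, taken
from Biopython's codon tables: ATA→Met, TGA→Trp, AGA/AGG→Ser, stops
TAA/TAG only. The bundled 64-row codon census doubles as a conformance
fixture: the table reader rejects any row whose amino-acid column
disagrees with table 5.

Codon-usage tables **include initiation and termination codons** — many
codon-usage tools exclude stops, but the published census counts them (its
TAA/TAG rows, 8 and 5, equal the 13 protein-coding genes). Only complete
codons are counted; a 1–2 nt trailing remainder attaches a warning instead
of being silently dropped. Nucleotides shared by overlapping genes count
once per gene they belong to, so the census total equals
Σ floor(span/3) over the genes (3,676 for the bundled coordinates — the
published census totals 3,671, a five-codon discrepancy that cannot be
resolved without the unpublished sequence). Incomplete (T/TA) stop codons
are not modelled; the source molecule has complete stops throughout.

## Non-coding scan and control-region proposal

Non-coding regions are the complement of the union of PCG/rRNA/tRNA
intervals, computed by exact interval arithmetic (sweep-line over interval
endpoints); union coverage plus summed non-coding lengths always equals
the genome length. Regions coinciding with an annotated non-coding feature
keep its name; others are reported as derived gaps. Coverage breakdowns
expose two overlap-attribution rules: *union* (each position once,
multi-category positions attributed by the fixed priority
PCG > rRNA > tRNA, so category fractions sum to 100% of coding) and
*per-category-with-overlap* (a position under two categories counts toward
both, so fractions can exceed 100%). For the bundled table the union rule
gives 91.22% coding; the published 92.1% is only reachable if the 133-nt
gap before the origin is ignored, and the published 79.31/15.24/6.62
category split matches neither rule exactly — the package reports both
rules side by side rather than reverse-engineering an undocumented
convention.

AT enrichment of a candidate control region is a Pearson χ² with 1 df on
its (A+T, G+C) counts. The default variant is a goodness-of-fit against
the genome-wide A+T fraction without continuity correction; a Yates
goodness-of-fit, a 2×2 region-vs-rest contingency test and its Yates
version are also exposed. With the printed inputs (71.27% of 442 nt
against a 64.02% genome) the variants give χ² ≈ 9.8–10.1 for the first
long region and ≈ 8.2–8.5 for the second; the published statistics (9.503
and 7.991) are not reproducible from the published rounded inputs under
any standard variant, and the package documents that discrepancy rather
than tuning to it. `propose_control_regions` flags non-coding regions of
at least `min_len` nt (default 200 — long enough that the two 442/394-nt
candidates are well powered while 19–131 nt gaps are not even tested)
whose A+T exceeds the genome's and whose test is significant at α (default
0.01). No multiple-testing correction is applied by default, matching the
source analysis; a Bonferroni option exists.

## Gene order

Orders are circular signed permutations; equality holds up to rotation and
up to whole-molecule reversal with orientation flip. Adjacencies use the
head/tail extremity model standard in the genome-rearrangement literature:
the adjacency between consecutive genes is the unordered pair {right
extremity of the first, left extremity of the second}, so an inverted gene
between unchanged neighbours costs two breakpoints and reversal symmetry
is automatic. Breakpoint distance is the number of adjacencies of one
order absent from the other after restriction to the common label set
(dropped labels are reported; the *S. maritima* order lacks six of the 22
canonical tRNAs). Shared adjacencies + breakpoints = common genes, an
identity asserted in tests.

Conserved blocks are maximal runs of ≥2 genes appearing with identical
relative order and orientation in both orders. With the default
`max_gap=0` this is a chain of shared signed adjacencies. `max_gap=k`
allows up to k intervening genes in either order between consecutive block
members, which is how figure-level conserved runs are usually drawn: in
the ground-plan comparison, the reference has a tRNA (trnT) inside the
minus-strand nad5–nad4 run and the *S. maritima* order has trnL2/trnV
inside the nad1–rRNA run, so the four published blocks (cox1–cox2;
trnF–nad5–trnH–nad4–nad4l–trnP; trnD–atp8–atp6; nad1–rrnL–rrnS) appear in
full only at `max_gap=1`; their strict cores appear at `max_gap=0`.
Displaced genes are those with neither flanking adjacency conserved
(strict sense), reported with their flanking context in both orders.
Nested genes (the tRNA-Gly gene inside cox3) are linearised by start
coordinate, ties by ascending end.

The reference arrangement ships as a small text fixture: the *Limulus
polyphemus* order (GenBank NC_003057), the usual exemplar of the arthropod
ground plan. It is user-replaceable via `--reference`.

## Synthetic genomes

The generator exists because the study's sequence is unpublished: it
produces a molecule with the published *structure* so that every pipeline
stage has a full-size, ground-truthed input. The default specification
uses the bundled coordinate skeleton (all 33 features, including the
same-strand and opposite-strand overlaps), the bundled codon-usage
distribution with stops removed for gene interiors, the published per-gene
start/stop codon assignments (pools ATT/ATG/ATA/ATC at 5/5/2/1 and
TAA/TAG at 8/5 serve genes without assignments), and per-category
composition targets: 68.58% A+T for rRNA, 71% for the two control-region
stand-ins, 64.02% for tRNAs and spacers, each split between A:T and C:G in
the ratios of the published plus strand.

Generation proceeds in phases: start/stop codons are pinned first (a
conflict between two pinned codons aborts before any sampling); gene
interiors are filled in start order, earlier features owning shared
segments, with overlap-constrained codons drawn conditionally on the fixed
bases; a repair pass resolves stop codons that arise in another gene's
reading frame through overlap, resampling only unpinned bases; RNA,
non-coding and spacer positions are then filled from their composition
targets. An overlap whose constraints cannot be satisfied is kept with a
warning in the truth record (the default skeleton needs no such
fallback). The truth record stores every assigned codon and realised
region composition.

Two sampling modes: **exact** (default) deals codons from a deck built by
largest-remainder apportionment of the target distribution and fills
regions with exact base-count apportionments, so censuses and compositions
are deterministic up to overlap repairs; **probabilistic** draws i.i.d.,
for calibration studies that need sampling noise. The RNG is numpy's
PCG64, named in every spec and truth record so seeds are portable; a spec
without a seed is rejected.

What the generator does *not* emulate: the published plus-strand skews
(+0.22/−0.33). Those printed fractions cannot be reconciled with the
published reading-frame codon usage plus the strand assignments — making
both hold simultaneously would force the non-coding remainder to ~62% A
and ~7% T — so the generator reproduces A+T content (within ±1 point of
64.02% across seeds) and codon/census structure, while its plus-strand
skews come out mild (≈ +0.04/−0.08). Passing tests on synthetic data
therefore demonstrate correctness of the arithmetic and calibration of the
tests, not distributional realism of real mitochondrial strand asymmetry;
there is also no evolutionary structure (no substitution model, no
indels).

Gene-order perturbation applies a stated number of uniform single-gene
translocations and segment inversions (with orientation flip) and returns
a move log sufficient for exact replay; each single-gene move changes at
most three adjacencies, giving the 3k breakpoint bound asserted in tests.

## Calibration studies and problem sizes

The type-I-error check of control-region proposal runs 1,000 seeded
replicates of a compact 3 kb skeleton (two 400-nt non-coding regions at
background composition, probabilistic mode) and requires the flagged
fraction to stay within α + 3·SE; the recovery check runs 100 seeded
full-size (14,983 bp) default-spec genomes and requires both planted
71%-AT regions — and nothing else — to be proposed in at least 95% of
replicates (in exact mode the planted composition makes recovery
deterministic). Breakpoint-distance correctness is checked exhaustively
against an independent both-direction scanning oracle over all 768 signed
circular orders of five genes, plus 400 seeded random pairs up to eight
genes; coverage arithmetic is checked against a per-position marking
oracle on the bundled table and 30 randomised annotations. These sizes
were chosen so the whole suite stays interactive while the Monte-Carlo
standard errors remain far below the tolerances tested.

## Numerical conventions

χ² p-values come from the χ² distribution with 1 df (scipy). Codon
ranking breaks count ties lexicographically. Apportionment of counts to
targets uses the largest-remainder method with stable ordering. Report
tables are tab-separated with `.` for missing values and a header comment
naming the coordinate convention.
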