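"""Signed circular gene orders and their comparison.

A mitochondrial gene order is modelled as a circular signed permutation of
gene labels.  Equality holds up to rotation and up to reversal of the whole
molecule with orientation flip (reading the other strand).

Adjacencies use the standard head/tail (extremity) model of the
genome-rearrangement literature: gene g exposes a tail (5' end) and a head
(3' end) in its reading direction, and the adjacency between consecutive
genes X, Y is the unordered pair {right extremity of X, left extremity of Y}.
Under this model an inverted gene between unchanged neighbours costs two
breakpoints, and reversal symmetry is automatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .annotation import CircularAnnotation

Signed = tuple[str, int]  # (label, +1 | -1)
Extremity = tuple[str, str]  # (label, "h" | "t")
Adjacency = frozenset  # of two extremities


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular ordered list of (gene label, orientation) pairs."""

    genes: tuple[Signed, ...]

    def __post_init__(self) -> None:
        labels = [g for g, _ in self.genes]
        if len(set(labels)) != len(labels):
            dupes = sorted({g for g in labels if labels.count(g) > 1})
            raise ValueError(f"duplicate gene labels: {dupes}")
        if any(s not in (+1, -1) for _, s in self.genes):
            raise ValueError("orientation must be +1 or -1")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_string(cls, text: str) -> "SignedGeneOrder":
        """Parse a one-line signed order ("cox1 cox2 -trnF ...")."""
        genes = []
        for token in text.split():
            if token.startswith("-"):
                genes.append((token[1:], -1))
            else:
                genes.append((token.lstrip("+"), +1))
        return cls(tuple(genes))

    def to_string(self) -> str:
        return " ".join(
            (g if s > 0 else f"-{g}") for g, s in self.genes
        )

    # -- basic structure ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.genes)

    def rotate(self, k: int) -> "SignedGeneOrder":
        n = len(self.genes)
        k %= n
        return SignedGeneOrder(self.genes[k:] + self.genes[:k])

    def reverse(self) -> "SignedGeneOrder":
        """Read the circle in the other direction (orientations flip)."""
        return SignedGeneOrder(tuple((g, -s) for g, s in reversed(self.genes)))

    def anchored(self, label: str) -> "SignedGeneOrder":
        """Rotate so that ``label`` comes first (display convenience)."""
        for i, (g, _) in enumerate(self.genes):
            if g == label:
                return self.rotate(i)
        raise KeyError(label)

    def restrict(self, labels: Iterable[str]) -> "SignedGeneOrder":
        keep = set(labels)
        return SignedGeneOrder(
            tuple((g, s) for g, s in self.genes if g in keep)
        )

    # -- equality up to rotation and reversal-with-flip ---------------------

    def _canonical(self) -> tuple[Signed, ...]:
        n = len(self.genes)
        if n == 0:
            return ()
        candidates = []
        for variant in (self.genes, self.reverse().genes):
            for k in range(n):
                candidates.append(variant[k:] + variant[:k])
        return min(candidates)

    def equivalent(self, other: "SignedGeneOrder") -> bool:
        return self._canonical() == other._canonical()

    # -- adjacency set -----------------------------------------------------

    def adjacencies(self) -> set[Adjacency]:
        """Unordered extremity pairs of consecutive genes (incl. wrap)."""
        n = len(self.genes)
        if n < 2:
            return set()
        out: set[Adjacency] = set()
        for i in range(n):
            (gx, sx) = self.genes[i]
            (gy, sy) = self.genes[(i + 1) % n]
            right: Extremity = (gx, "h" if sx > 0 else "t")
            left: Extremity = (gy, "t" if sy > 0 else "h")
            out.add(frozenset((right, left)))
        return out


def to_signed_order(ann: CircularAnnotation) -> SignedGeneOrder:
    """Gene order of an annotation: genes by ascending start, NC excluded.

    Nested or overlapping genes are linearised by start coordinate (ties by
    ascending end).  Unstranded coding features default to +.
    """
    genes = []
    for f in ann:  # CircularAnnotation sorts by (start, end, name)
        if not f.is_coding:
            continue
        genes.append((f.name, -1 if f.strand == "-" else +1))
    return SignedGeneOrder(tuple(genes))


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """A maximal conserved run, reported in the first order's reading."""

    genes: tuple[Signed, ...]
    reversed_in_other: bool = False

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OrderComparison:
    common_labels: frozenset[str]
    dropped_from_first: frozenset[str]
    dropped_from_second: frozenset[str]
    shared_adjacencies: int
    breakpoints: int
    blocks: tuple[Block, ...]
    displaced: tuple[tuple[str, dict], ...]


def _restricted_pair(
    o1: SignedGeneOrder, o2: SignedGeneOrder
) -> tuple[SignedGeneOrder, SignedGeneOrder, frozenset[str]]:
    common = o1.labels & o2.labels
    if len(common) < 2:
        raise ValueError(
            f"common label set has {len(common)} gene(s); need at least 2"
        )
    return o1.restrict(common), o2.restrict(common), frozenset(common)


def breakpoint_distance(o1: SignedGeneOrder, o2: SignedGeneOrder) -> int:
    """Number of signed adjacencies of ``o1`` absent from ``o2``.

    Both orders are restricted to their common label set first.  The count
    is invariant to rotation of either order and to whole-molecule reversal
    with orientation flip, is symmetric, and satisfies
    shared + breakpoints = |common label set|.
    """
    r1, r2, _ = _restricted_pair(o1, o2)
    a1, a2 = r1.adjacencies(), r2.adjacencies()
    return len(a1 - a2)


def conserved_blocks(
    o1: SignedGeneOrder,
    o2: SignedGeneOrder,
    max_gap: int = 0,
    exclude: Iterable[str] = (),
) -> list[Block]:
    """Maximal runs of >= 2 genes with identical relative order/orientation.

    With ``max_gap=0`` (default) a block is a chain of shared signed
    adjacencies — consecutive genes in both orders.  ``max_gap=g`` allows up
    to ``g`` intervening genes in either order between consecutive block
    members, which recovers figure-level blocks interrupted by single
    translocated tRNAs.  ``exclude`` drops labels from both orders before
    the scan.
    """
    r1, r2, common = _restricted_pair(o1, o2)
    if exclude:
        keep = common - set(exclude)
        if len(keep) < 2:
            return []
        r1, r2 = r1.restrict(keep), r2.restrict(keep)
    n = len(r1)
    pos2 = {g: i for i, (g, _) in enumerate(r2.genes)}
    sign1 = {g: s for g, s in r1.genes}
    sign2 = {g: s for g, s in r2.genes}

    def link(x: str, y: str, flag: int) -> bool:
        """Can y follow x in a block read along r1, given orientation flag?

        flag = +1: the block appears in r2 in the same direction
        (orientations equal); flag = -1: the block is reversed in r2
        (orientations flipped, r2 positions descending).
        """
        if sign2[x] != flag * sign1[x] or sign2[y] != flag * sign1[y]:
            return False
        if flag > 0:
            d = (pos2[y] - pos2[x]) % n
        else:
            d = (pos2[x] - pos2[y]) % n
        return 1 <= d <= max_gap + 1

    genes1 = [g for g, _ in r1.genes]

    def pair_flag(x: str, y: str) -> int | None:
        """Orientation flag under which y can follow x, if any."""
        for f in (+1, -1):
            if link(x, y, f):
                return f
        return None

    used: set[str] = set()

    def grow(start_idx: int) -> tuple[list[str], int]:
        chain = [genes1[start_idx]]
        flag = 0
        i = start_idx
        while len(chain) < n:
            nxt = None
            for gap in range(0, max_gap + 1):
                j = (i + 1 + gap) % n
                y = genes1[j]
                if y in used or y == chain[0]:
                    continue
                f = pair_flag(chain[-1], y)
                if f is None or (flag and f != flag):
                    continue
                nxt = (j, y, f)
                break
            if nxt is None:
                break
            i, y, f = nxt
            flag = flag or f
            chain.append(y)
            used.add(y)
        return chain, flag

    def has_predecessor(idx: int) -> bool:
        y = genes1[idx]
        for gap in range(0, max_gap + 1):
            x = genes1[(idx - 1 - gap) % n]
            if x != y and pair_flag(x, y) is not None:
                return True
        return False

    starts = [i for i in range(n) if not has_predecessor(i)]
    blocks: list[Block] = []
    if not starts:
        # every gene is preceded by a link: the whole circle is conserved
        used.add(genes1[0])
        chain, flag = grow(0)
        if len(chain) >= 2:
            return [
                Block(tuple((x, sign1[x]) for x in chain), flag < 0)
            ]
        return []
    # grow chains from true chain heads first, then from any leftovers
    for idx in starts + [i for i in range(n) if genes1[i] not in used]:
        g = genes1[idx]
        if g in used:
            continue
        used.add(g)
        chain, flag = grow(idx)
        if len(chain) >= 2:
            blocks.append(
                Block(
                    tuple((x, sign1[x]) for x in chain),
                    reversed_in_other=(flag < 0),
                )
            )
    return blocks


def displaced_genes(
    o1: SignedGeneOrder, o2: SignedGeneOrder
) -> list[tuple[str, dict]]:
    """Genes with neither flanking adjacency conserved, with their contexts.

    Computed on the common label set with strict (gap-free) adjacencies.
    Each entry carries the gene's neighbours in both orders so the novel
    flanking context is inspectable.
    """
    r1, r2, _ = _restricted_pair(o1, o2)
    a2 = r2.adjacencies()
    n = len(r1)
    out = []
    pos2 = {g: i for i, (g, _) in enumerate(r2.genes)}
    for i, (g, s) in enumerate(r1.genes):
        prev_g, prev_s = r1.genes[(i - 1) % n]
        next_g, next_s = r1.genes[(i + 1) % n]
        pred = frozenset(
            (
                (prev_g, "h" if prev_s > 0 else "t"),
                (g, "t" if s > 0 else "h"),
            )
        )
        succ = frozenset(
            (
                (g, "h" if s > 0 else "t"),
                (next_g, "t" if next_s > 0 else "h"),
            )
        )
        if pred not in a2 and succ not in a2:
            j = pos2[g]
            out.append(
                (
                    g,
                    {
                        "first_order_context": (prev_g, next_g),
                        "second_order_context": (
                            r2.genes[(j - 1) % n][0],
                            r2.genes[(j + 1) % n][0],
                        ),
                    },
                )
            )
    return out


def compare_orders(
    o1: SignedGeneOrder, o2: SignedGeneOrder, max_gap: int = 0
) -> OrderComparison:
    """Full comparison: shared adjacencies, breakpoints, blocks, displaced."""
    r1, r2, common = _restricted_pair(o1, o2)
    a1, a2 = r1.adjacencies(), r2.adjacencies()
    shared = len(a1 & a2)
    return OrderComparison(
        common_labels=common,
        dropped_from_first=frozenset(o1.labels - common),
        dropped_from_second=frozenset(o2.labels - common),
        shared_adjacencies=shared,
        breakpoints=len(a1) - shared,
        blocks=tuple(conserved_blocks(o1, o2, max_gap=max_gap)),
        displaced=tuple(displaced_genes(o1, o2)),
    )


def block_diagram(comparison: OrderComparison) -> str:
    """Human-readable text rendering of conserved blocks."""
    lines = [
        f"common genes: {len(comparison.common_labels)}; "
        f"shared adjacencies: {comparison.shared_adjacencies}; "
        f"breakpoints: {comparison.breakpoints}"
    ]
    for b in comparison.blocks:
        arrow = "<->" if b.reversed_in_other else "-->"
        genes = " ".join(g if s > 0 else f"-{g}" for g, s in b.genes)
        lines.append(f"  [{arrow}] {genes}")
    if comparison.displaced:
        lines.append(
            "displaced: " + " ".join(g for g, _ in comparison.displaced)
        )
    return "\n".join(lines)


def ground_plan_order() -> SignedGeneOrder:
    """The arthropod ground-plan order (Limulus polyphemus), bundled."""
    text = (
        resources.files("mitoprofile.data")
        .joinpath("limulus_ground_plan.txt")
        .read_text()
    )
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ]
    return SignedGeneOrder.from_string(" ".join(lines))
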