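"""Base composition, A+T content and strand-skew statistics.

Skews measure compositional asymmetry between the two strands of the
molecule, computed on the reported strand:

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

Both lie in [-1, +1]; 0 means the bases of a pair are equally frequent.
Fractions are reported in percent of non-N positions; N positions are
counted but excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import GeneFeature, feature_intervals
from .errors import RangeError, SequenceError, UndefinedStatisticError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CompositionProfile:
    """Per-base counts plus derived fractions, A+T content and skews."""

    a: int
    c: int
    g: int
    t: int
    n: int = 0

    @property
    def total(self) -> int:
        """Non-N positions (the denominator for all fractions)."""
        return self.a + self.c + self.g + self.t

    def fraction(self, base: str) -> float:
        """Fraction of a base in percent of non-N positions."""
        if self.total == 0:
            raise UndefinedStatisticError("profile has no unambiguous bases")
        return 100.0 * getattr(self, base.lower()) / self.total

    @property
    def at_content(self) -> float:
        """A+T content in percent; equals fraction(A) + fraction(T)."""
        return self.fraction("a") + self.fraction("t")

    @property
    def at_skew(self) -> float:
        if self.a + self.t == 0:
            raise UndefinedStatisticError("AT-skew undefined: A+T = 0")
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float:
        if self.g + self.c == 0:
            raise UndefinedStatisticError("GC-skew undefined: G+C = 0")
        return (self.g - self.c) / (self.g + self.c)

    def __add__(self, other: "CompositionProfile") -> "CompositionProfile":
        return CompositionProfile(
            self.a + other.a,
            self.c + other.c,
            self.g + other.g,
            self.t + other.t,
            self.n + other.n,
        )

    @classmethod
    def from_fractions(
        cls, a: float, c: float, g: float, t: float, scale: int = 10_000_000
    ) -> "CompositionProfile":
        """Build a profile from printed percentages.

        Skews and A+T content are scale-free, so any large ``scale`` gives
        the same derived statistics as the underlying counts would.
        """
        total = a + c + g + t
        if total <= 0:
            raise UndefinedStatisticError("fractions must sum to > 0")
        return cls(
            a=round(scale * a / total),
            c=round(scale * c / total),
            g=round(scale * g / total),
            t=round(scale * t / total),
        )


def base_composition(seq: str, strand: str = "+") -> CompositionProfile:
    """Composition profile of ``seq`` (or of its reverse complement for "-").

    The sequence must be non-empty and over the alphabet ACGTN (case
    insensitive); any other character raises a :class:`SequenceError`
    naming the offending 1-based position.
    """
    if not seq:
        raise SequenceError("empty sequence")
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        pos = next(i for i, ch in enumerate(s, start=1) if ch in bad)
        raise SequenceError(
            f"non-IUPAC character {s[pos - 1]!r} at position {pos}"
        )
    if strand == "-":
        s = reverse_complement(s)
    elif strand != "+":
        raise SequenceError(f"bad strand {strand!r}")
    return CompositionProfile(
        a=s.count("A"), c=s.count("C"), g=s.count("G"), t=s.count("T"),
        n=s.count("N"),
    )


def skews(profile: CompositionProfile) -> tuple[float, float]:
    """(AT-skew, GC-skew) of a profile.

    Undefined skews (A+T = 0 or G+C = 0) raise
    :class:`UndefinedStatisticError` rather than silently returning 0.
    """
    return profile.at_skew, profile.gc_skew


def extract_region(
    seq: str, start: int, end: int, strand: str = "+", wrap: bool = False
) -> str:
    """Slice [start, end] (1-based inclusive) from a circular sequence.

    ``wrap=True`` (or start > end) reads across the origin.  Minus strand
    returns the reverse complement of the plus-strand slice.
    """
    L = len(seq)
    if not (1 <= start <= L and 1 <= end <= L):
        raise RangeError(f"region [{start},{end}] outside [1,{L}]")
    if wrap or start > end:
        piece = seq[start - 1 :] + seq[: end]
    else:
        piece = seq[start - 1 : end]
    return reverse_complement(piece.upper()) if strand == "-" else piece.upper()


def region_composition(
    seq: str,
    region: GeneFeature | tuple[int, int],
    strand: str | None = None,
) -> CompositionProfile:
    """Composition of an annotated feature or a (start, end) coordinate pair.

    For a :class:`GeneFeature` the feature's own strand is used unless
    overridden; coordinate pairs default to the plus strand and may wrap
    (start > end reads across the origin).
    """
    if isinstance(region, GeneFeature):
        intervals = feature_intervals(region, len(seq))
        use_strand = strand if strand is not None else (
            region.strand if region.strand in {"+", "-"} else "+"
        )
        piece = "".join(
            seq[s - 1 : e].upper() for s, e in intervals
        )
        if use_strand == "-":
            piece = reverse_complement(piece)
        return base_composition(piece)
    start, end = region
    use_strand = strand if strand is not None else "+"
    return base_composition(extract_region(seq, start, end, use_strand))
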