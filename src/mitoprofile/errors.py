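"""Exception hierarchy shared across the package."""


class MitoprofileError(Exception):
    """Base class for all package-specific errors."""


class AnnotationParseError(MitoprofileError, ValueError):
    """A feature table / GFF3 / GenBank record could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CoordinateError(MitoprofileError, ValueError):
    """Feature coordinates are internally inconsistent (e.g. start > end)."""


class RangeError(MitoprofileError, ValueError):
    """Coordinates fall outside [1, genome_length]."""


class SequenceError(MitoprofileError, ValueError):
    """A nucleotide sequence is empty or contains non-IUPAC characters."""


class UndefinedStatisticError(MitoprofileError, ArithmeticError):
    """A statistic is undefined for the given counts (e.g. GC-skew with G+C=0)."""


class InfeasibleSpecError(MitoprofileError, ValueError):
    """A synthetic-genome specification cannot be realised."""
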