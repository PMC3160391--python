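"""Genomic intervals, coordinate conventions and reference sequences.

Internally every interval is 0-based half-open ([start, end), length =
``end - start``).  Genome annotation reports traditionally print 1-based
closed coordinates (length = ``end - start + 1``); conversion happens only
at I/O and report boundaries via :func:`closed_to_halfopen` /
:func:`halfopen_to_closed`.
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class IntervalError(ValueError):
    """Raised for invalid or incomparable genomic intervals."""


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named reference.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    ref_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise IntervalError(f"negative start {self.start} on {self.ref_id!r}")
        if self.end <= self.start:
            raise IntervalError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.ref_id!r}"
            )
        if self.strand not in STRANDS:
            raise IntervalError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        """Half-open length, ``end - start``."""
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.ref_id == other.ref_id and (
            min(self.end, other.end) - max(self.start, other.start) > 0
        )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals on the same reference.

    Symmetric in its arguments; disjoint intervals give 0.  Intervals on
    different references are incomparable and raise :class:`IntervalError`.
    """
    if a.ref_id != b.ref_id:
        raise IntervalError(
            f"cannot overlap intervals on different references: {a.ref_id!r} vs {b.ref_id!r}"
        )
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def closed_length(start1: int, end1: int) -> int:
    """Length of a 1-based closed span, ``end1 - start1 + 1``.

    This is the convention behind printed element lengths such as a 195 bp
    SINE at positions 37,204-37,398.
    """
    if end1 < start1:
        raise IntervalError(f"closed interval end {end1} precedes start {start1}")
    return end1 - start1 + 1


def closed_to_halfopen(start1: int, end1: int) -> tuple[int, int]:
    """Convert 1-based closed coordinates to 0-based half-open."""
    if start1 < 1:
        raise IntervalError(f"1-based start must be >= 1, got {start1}")
    if end1 < start1:
        raise IntervalError(f"closed interval end {end1} precedes start {start1}")
    return start1 - 1, end1


def halfopen_to_closed(start0: int, end0: int) -> tuple[int, int]:
    """Convert 0-based half-open coordinates to 1-based closed."""
    if start0 < 0 or end0 <= start0:
        raise IntervalError(f"invalid half-open interval [{start0}, {end0})")
    return start0 + 1, end0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSequence:
    """A named uppercase nucleotide sequence over {A,C,G,T,N}.

    Lowercase input is folded to uppercase on construction.  ``N`` bases are
    permitted but are never counted as matches by the mapper.
    """

    ref_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise SequenceAlphabetError(f"empty sequence for {self.ref_id!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise SequenceAlphabetError(
                f"illegal character {seq[pos]!r} at position {pos} in {self.ref_id!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def interval(self, strand: str = ".") -> GenomicInterval:
        """The interval spanning the whole sequence."""
        return GenomicInterval(self.ref_id, 0, len(self.sequence), strand)
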