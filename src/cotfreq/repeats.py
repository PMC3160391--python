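"""Sequence-structure scanners: perfect tandem repeats, self dot matrix,
tandem-unit periodicity, and conserved-difference columns in an MSA.

These are the annotation tools used when characterising a repeat-dense
genomic region: microsatellite-style perfect tandem repeats (1-6 bp
motifs), a word-match self-comparison dot matrix that makes rDNA-like
tandem cassettes visible as parallel off-diagonals, and a lag-histogram
period estimator that turns those off-diagonals into a repeat-unit length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval


class RepeatScanError(ValueError):
    pass


@dataclass(frozen=True)
class TandemRepeat:
    interval: GenomicInterval
    motif: str  # lexicographically minimal rotation
    copies: float  # possibly fractional
    total_length: int


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for p in range(1, m):
        if m % p == 0 and motif == motif[:p] * (m // p):
            return False
    return True


def _true_runs(mask: np.ndarray) -> Iterable[tuple[int, int]]:
    """(start, stop) pairs of maximal True runs in a boolean array."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return zip(edges[::2], edges[1::2])


def find_perfect_tandem_repeats(
    seq: str,
    motif_len_range: tuple[int, int] = (1, 6),
    min_total_length: int = 12,
    min_copies: float = 2.0,
    ref_id: str = "seq",
) -> list:
    """Maximal runs of exact motif repetition, sorted by start.

    The shortest motif wins ("AAAAAA" is A x6, never AA x3); motifs are
    reported as their lexicographically minimal rotation, and a run fully
    contained in a run of shorter motif is suppressed.  Motifs containing
    N are not reported.
    """
    lo, hi = motif_len_range
    if not 1 <= lo <= hi:
        raise RepeatScanError(f"invalid motif length range {motif_len_range}")
    if not seq:
        raise RepeatScanError("empty sequence")
    seq = seq.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    found: list[TandemRepeat] = []
    for m in range(lo, hi + 1):
        if arr.size < 2 * m:
            continue
        eq = arr[:-m] == arr[m:]
        for i, j in _true_runs(eq):
            span = (j - i) + m  # run covers seq[i : j + m]
            if span < min_total_length or span / m < min_copies:
                continue
            motif = seq[i : i + m]
            if not _is_primitive(motif) or set(motif) - set("ACGT"):
                continue
            found.append(
                TandemRepeat(
                    interval=GenomicInterval(ref_id, int(i), int(i + span)),
                    motif=canonical_rotation(motif),
                    copies=span / m,
                    total_length=int(span),
                )
            )
    # suppress runs contained in an equal-or-longer run of a shorter motif
    found.sort(key=lambda r: (len(r.motif), r.interval.start))
    kept: list[TandemRepeat] = []
    for r in found:
        contained = any(
            len(k.motif) < len(r.motif)
            and k.interval.start <= r.interval.start
            and k.interval.end >= r.interval.end
            for k in kept
        )
        if not contained:
            kept.append(r)
    kept.sort(key=lambda r: (r.interval.start, r.interval.end))
    return kept


@dataclass(frozen=True)
class DotMatrix:
    """Sparse same-strand self-comparison dot matrix.

    A point (x, y) is present iff the ``word``-long windows at x and y
    agree in at least ``stringency`` positions (N never matches).  The set
    is symmetric and contains the main diagonal.
    """

    word: int
    stringency: int
    n: int
    points: frozenset

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("x\ty\n")
            for x, y in sorted(self.points):
                fh.write(f"{x}\t{y}\n")


def _lag_window_hits(arr: np.ndarray, lag: int, word: int, stringency: int) -> np.ndarray:
    """Window start positions x where windows x and x+lag match well enough."""
    eq = (arr[:-lag] == arr[lag:]) & (arr[:-lag] < 255)
    valid = (arr[:-lag] != ord("N")) & (arr[lag:] != ord("N"))
    m = (eq & valid).astype(np.int32)
    if m.size < word:
        return np.empty(0, dtype=np.int64)
    c = np.concatenate(([0], np.cumsum(m)))
    wsum = c[word:] - c[:-word]
    return np.flatnonzero(wsum >= stringency)


def self_dot_matrix(seq: str, word: int = 11, stringency: int = 9) -> DotMatrix:
    if word < 4:
        raise RepeatScanError(f"word must be >= 4, got {word}")
    if stringency > word:
        raise RepeatScanError("stringency cannot exceed word length")
    seq = seq.upper()
    n = len(seq)
    if n < word:
        return DotMatrix(word, stringency, n, frozenset())
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    pts = {(i, i) for i in range(n - word + 1)}
    for lag in range(1, n - word + 1):
        for x in _lag_window_hits(arr, lag, word, stringency):
            pts.add((int(x), int(x) + lag))
            pts.add((int(x) + lag, int(x)))
    return DotMatrix(word, stringency, n, frozenset(pts))


def lag_match_counts(
    seq: str, word: int = 11, stringency: int = 9, max_lag: int | None = None
) -> np.ndarray:
    """Off-diagonal match-window counts per lag (index = lag, entry 0 = 0)."""
    seq = seq.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size
    if max_lag is None:
        max_lag = n - word
    max_lag = min(max_lag, n - word)
    counts = np.zeros(max(max_lag + 1, 1), dtype=np.int64)
    for lag in range(1, max_lag + 1):
        counts[lag] = _lag_window_hits(arr, lag, word, stringency).size
    return counts


def estimate_unit_period(
    seq: str,
    word: int = 11,
    stringency: int = 9,
    min_fraction: float = 0.6,
    min_windows: int = 20,
) -> int | None:
    """Repeat-cassette length of a tandem array, or None.

    Scans lags up to half the sequence length and returns the smallest lag
    at which the number of matching word-windows exceeds ``min_fraction``
    of the maximum possible at that lag (lags offering fewer than
    ``min_windows`` windows are ignored).  Three or more exact copies of a
    unit of length U give the exact answer U.
    """
    seq = seq.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for lag in range(1, n // 2 + 1):
        windows = n - lag - word + 1
        if windows < min_windows:
            break
        hits = _lag_window_hits(arr, lag, word, stringency).size
        if hits / windows >= min_fraction:
            return lag
    return None


GAPLIKE = set("-.NRYSWKMBDHV")  # gaps plus ambiguity codes, excluded from sites


@dataclass(frozen=True)
class ConservedDifferenceSite:
    column: int  # 0-based alignment column
    residue_a: str
    residue_b: str


def conserved_difference_sites(
    alignment: Sequence, group_a: Sequence[str], group_b: Sequence[str]
) -> list:
    """Columns fixed within each group but different between groups.

    ``alignment`` is a sequence of (id, aligned_sequence) pairs (or objects
    with ``id``/``seq``, e.g. Biopython SeqRecords); groups are id lists.
    A column qualifies iff every group-A residue is one identical non-gap
    base, every group-B residue is one identical non-gap base, and the two
    bases differ.  N and ambiguity codes count as gaps.  The result is
    invariant to row order within groups.
    """
    rows = {}
    for entry in alignment:
        if hasattr(entry, "id") and hasattr(entry, "seq"):
            rows[entry.id] = str(entry.seq).upper()
        else:
            rid, seq = entry
            rows[rid] = seq.upper()
    if not group_a or not group_b:
        raise RepeatScanError("both groups must be non-empty")
    missing = [rid for rid in (*group_a, *group_b) if rid not in rows]
    if missing:
        raise RepeatScanError(f"ids not in alignment: {missing}")
    lengths = {len(rows[rid]) for rid in (*group_a, *group_b)}
    if len(lengths) != 1:
        raise RepeatScanError(f"ragged alignment: row lengths {sorted(lengths)}")
    (ncol,) = lengths

    def _mat(ids: Sequence[str]) -> np.ndarray:
        return np.array([list(rows[rid]) for rid in ids])

    a, b = _mat(group_a), _mat(group_b)
    sites = []
    for col in range(ncol):
        ca, cb = set(a[:, col]), set(b[:, col])
        if len(ca) != 1 or len(cb) != 1:
            continue
        ra, rb = str(next(iter(ca))), str(next(iter(cb)))
        if ra in GAPLIKE or rb in GAPLIKE or ra not in "ACGT" or rb not in "ACGT":
            continue
        if ra != rb:
            sites.append(ConservedDifferenceSite(col, ra, rb))
    return sites
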