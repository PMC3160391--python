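"""Seed-and-extend read mapping under explicit identity/coverage thresholds.

The mapper re-implements the strict contract used for Cot-read-to-BAC
comparisons — by default a read is mapped only if it can be placed at 100%
identity with at least 90% of its bases aligned.  k-mer seeds anchor
candidate diagonals on both strands; ungapped extension over the full read
(clipped only at reference ends) scores matches; the best qualifying
placement is the primary alignment, with ties broken deterministically by
lowest reference coordinate then ``+`` strand.  All tied-best placements
are retained on the record so downstream element counting is not biased
against repeat copies by tie-breaking.

Definitions (stated because upstream tools rarely agree):
identity = matches / aligned_read_bases (soft-clipped bases excluded);
read_coverage = aligned_read_bases / read_length (raw read length).
``N`` bases never count as matches.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, ReferenceSequence

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

UNMAPPED_TOO_SHORT = "read_shorter_than_seed_word"
UNMAPPED_NO_PLACEMENT = "no_qualifying_placement"


class MappingError(ValueError):
    pass


class SamRecordError(ValueError):
    pass


@dataclass(frozen=True)
class MappingConfig:
    min_identity: float = 1.0
    min_read_coverage: float = 0.9
    seed_word: int = 16
    max_hits_reported: int = 1000
    #: seeds occurring more often than this in the reference are masked
    #: (standard over-represented-seed filtering; keeps low-complexity reads
    #: from exploding the candidate list)
    max_seed_hits: int = 5000

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_read_coverage"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise MappingError(f"{name} must be in (0, 1], got {v}")
        if self.seed_word < 8:
            raise MappingError(f"seed_word must be >= 8, got {self.seed_word}")


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary read placement on a reference."""

    read_id: str
    target: GenomicInterval
    strand: str
    matches: int
    aligned_read_bases: int
    read_length: int
    tied_targets: tuple = ()  # ((start, end), ...) of all tied-best placements

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_read_bases

    @property
    def read_coverage(self) -> float:
        return self.aligned_read_bases / self.read_length


@dataclass
class MappingResult:
    ref_id: str
    reference_length: int
    records: list
    unmapped: list  # [(read_id, reason), ...]

    @property
    def mapped_count(self) -> int:
        return len(self.records)

    @property
    def total_reads(self) -> int:
        return len(self.records) + len(self.unmapped)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "read_id\tref_id\tstart\tend\tstrand\tmatches\t"
                "aligned_read_bases\tread_length\tidentity\tread_coverage\ttied_targets\n"
            )
            for r in self.records:
                tied = ";".join(f"{s}-{e}" for s, e in r.tied_targets)
                fh.write(
                    f"{r.read_id}\t{r.target.ref_id}\t{r.target.start}\t{r.target.end}\t"
                    f"{r.strand}\t{r.matches}\t{r.aligned_read_bases}\t{r.read_length}\t"
                    f"{r.identity:.6g}\t{r.read_coverage:.6g}\t{tied}\n"
                )


def alignments_from_tsv(path: str | Path) -> list:
    """Read back an alignment table written by :meth:`MappingResult.to_tsv`."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            tied = tuple(
                tuple(int(x) for x in t.split("-"))
                for t in f[idx["tied_targets"]].split(";")
                if t
            )
            records.append(
                AlignmentRecord(
                    read_id=f[idx["read_id"]],
                    target=GenomicInterval(
                        f[idx["ref_id"]],
                        int(f[idx["start"]]),
                        int(f[idx["end"]]),
                        f[idx["strand"]],
                    ),
                    strand=f[idx["strand"]],
                    matches=int(f[idx["matches"]]),
                    aligned_read_bases=int(f[idx["aligned_read_bases"]]),
                    read_length=int(f[idx["read_length"]]),
                    tied_targets=tied,
                )
            )
    return records


def encode(seq: str) -> np.ndarray:
    """2-bit-style codes: A=0 C=1 G=2 T=3, anything else (N) = 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = codes[::-1].copy()
    acgt = rc < 4
    rc[acgt] = 3 - rc[acgt]
    return rc


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 packed k-mer codes and a validity mask (no N in window)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        vals = vals * np.uint64(4) + np.minimum(codes[j : j + n], 3).astype(np.uint64)
    ncount = np.concatenate(([0], np.cumsum(codes == 4)))
    valid = (ncount[k:] - ncount[:-k]) == 0
    return vals, valid


class ReferenceIndex:
    """Sorted k-mer index of a reference for seed lookup."""

    def __init__(self, reference: ReferenceSequence, seed_word: int = 16):
        if seed_word < 4:
            raise MappingError("seed_word must be >= 4")
        self.reference = reference
        self.seed_word = seed_word
        self.codes = encode(reference.sequence)
        vals, valid = _kmer_codes(self.codes, seed_word)
        pos = np.nonzero(valid)[0]
        keys = vals[valid]
        order = np.argsort(keys, kind="stable")
        self._keys = keys[order]
        self._pos = pos[order]

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._keys, code, side="left")
        hi = np.searchsorted(self._keys, code, side="right")
        return self._pos[lo:hi]


def _seed_offsets(read_len: int, k: int, step: int) -> list:
    offs = list(range(0, read_len - k + 1, step))
    last = read_len - k
    if offs and offs[-1] != last:
        offs.append(last)
    return offs


def _candidate_starts(
    index: ReferenceIndex, rcodes: np.ndarray, step: int, max_seed_hits: int = 5000
) -> np.ndarray:
    k = index.seed_word
    vals, valid = _kmer_codes(rcodes, k)
    diags = []
    for o in _seed_offsets(rcodes.size, k, step):
        if valid[o]:
            hits = index.lookup(vals[o])
            if 0 < hits.size <= max_seed_hits:
                diags.append(hits.astype(np.int64) - o)
    if not diags:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(diags))


def _score_starts(
    ref_codes: np.ndarray, rcodes: np.ndarray, starts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ungapped scoring of candidate placements.

    Returns (matches, aligned_read_bases) per candidate; the alignment is
    the read laid on the reference at the candidate start, clipped at
    reference ends.  N on either side never matches.
    """
    L = ref_codes.size
    rlen = rcodes.size
    idx = starts[:, None] + np.arange(rlen)[None, :]
    inb = (idx >= 0) & (idx < L)
    ref = ref_codes[np.where(inb, idx, 0)]
    read = rcodes[None, :]
    match = inb & (ref == read) & (ref < 4) & (read < 4)
    return match.sum(axis=1), inb.sum(axis=1)


def _normalize_reads(reads: Iterable) -> list:
    out = []
    for r in reads:
        if hasattr(r, "read_id") and hasattr(r, "sequence"):
            out.append((r.read_id, r.sequence))
        else:
            rid, seq = r
            out.append((rid, seq))
    return out


def map_reads(
    reads: Iterable,
    reference: ReferenceSequence,
    config: MappingConfig | None = None,
    seed: int = 0,
    index: ReferenceIndex | None = None,
) -> MappingResult:
    """Map reads to a reference; at most one primary placement per read.

    ``reads`` is an iterable of ``(read_id, sequence)`` pairs or objects
    with ``read_id``/``sequence`` attributes.  The mapper is fully
    deterministic; ``seed`` is accepted for interface uniformity with the
    simulation stages and does not influence the result.
    """
    del seed
    config = config or MappingConfig()
    pairs = _normalize_reads(reads)
    if not pairs:
        raise MappingError("no reads supplied")
    if not reference.sequence:
        raise MappingError("empty reference")
    if index is None:
        index = ReferenceIndex(reference, config.seed_word)
    elif index.seed_word != config.seed_word:
        raise MappingError("prebuilt index seed_word differs from config")
    ref_codes = index.codes
    L = ref_codes.size
    step = config.seed_word  # non-overlapping seeds

    records: list = []
    unmapped: list = []
    for read_id, seq in pairs:
        rlen = len(seq)
        if rlen < config.seed_word:
            unmapped.append((read_id, UNMAPPED_TOO_SHORT))
            continue
        min_aligned = math.ceil(config.min_read_coverage * rlen - 1e-9)
        fwd = encode(seq)
        best: list = []  # (matches, start_clip, end_clip, strand)
        best_matches = -1
        for strand, rcodes in (("+", fwd), ("-", revcomp_codes(fwd))):
            starts = _candidate_starts(index, rcodes, step, config.max_seed_hits)
            if starts.size == 0:
                continue
            starts = starts[(starts > -rlen) & (starts < L)]
            if starts.size == 0:
                continue
            matches, aligned = _score_starts(ref_codes, rcodes, starts)
            ok = (aligned >= min_aligned) & (
                matches >= config.min_identity * aligned - 1e-9
            )
            for s, m, a in zip(starts[ok], matches[ok], aligned[ok]):
                m = int(m)
                if m < best_matches:
                    continue
                entry = (m, max(int(s), 0), min(int(s) + rlen, L), strand)
                if m > best_matches:
                    best = [entry]
                    best_matches = m
                else:
                    best.append(entry)
        if not best:
            unmapped.append((read_id, UNMAPPED_NO_PLACEMENT))
            continue
        best.sort(key=lambda e: (e[1], e[3] != "+", e[2]))
        m, s0, e0, strand = best[0]
        aligned0 = e0 - s0
        tied = tuple((s, e) for _, s, e, _ in best[: config.max_hits_reported])
        records.append(
            AlignmentRecord(
                read_id=read_id,
                target=GenomicInterval(reference.ref_id, s0, e0, strand),
                strand=strand,
                matches=m,
                aligned_read_bases=aligned0,
                read_length=rlen,
                tied_targets=tied,
            )
        )
    return MappingResult(
        ref_id=reference.ref_id,
        reference_length=L,
        records=records,
        unmapped=unmapped,
    )


def find_element_copies(
    reference: ReferenceSequence,
    probe: str,
    min_identity: float = 0.84,
    min_coverage: float = 0.69,
    seed_word: int = 9,
    seed_step: int = 3,
) -> list:
    """Locate diverged copies of a probe element by similarity thresholds.

    Defaults mirror SINE annotation practice for the Ruka family: identity
    above 84% and probe coverage above 69%.  Hits are best-scoring,
    non-overlapping (greedy by score), searched on both strands.
    """
    if not probe:
        raise MappingError("empty probe")
    if len(probe) < seed_word:
        raise MappingError(f"probe shorter than seed word ({seed_word})")
    index = ReferenceIndex(reference, seed_word)
    ref_codes = index.codes
    L = ref_codes.size
    plen = len(probe)
    min_aligned = math.ceil(min_coverage * plen - 1e-9)
    fwd = encode(probe)
    hits: list = []  # (matches, start_clip, end_clip, strand)
    for strand, pcodes in (("+", fwd), ("-", revcomp_codes(fwd))):
        starts = _candidate_starts(index, pcodes, seed_step)
        if starts.size == 0:
            continue
        starts = starts[(starts > -plen) & (starts < L)]
        if starts.size == 0:
            continue
        matches, aligned = _score_starts(ref_codes, pcodes, starts)
        ok = (aligned >= min_aligned) & (matches >= min_identity * aligned - 1e-9)
        for s, m in zip(starts[ok], matches[ok]):
            hits.append((int(m), max(int(s), 0), min(int(s) + plen, L), strand))
    hits.sort(key=lambda h: (-h[0], h[1], h[3] != "+"))
    chosen: list = []
    for m, s, e, strand in hits:
        if any(min(e, ce) - max(s, cs) > 0 for cs, ce, _ in chosen):
            continue
        chosen.append((s, e, strand))
    chosen.sort()
    return [
        GenomicInterval(reference.ref_id, s, e, strand) for s, e, strand in chosen
    ]


_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _matches_from_md(md: str) -> int:
    matched = 0
    for num, _dele, _sub in _MD_TOKEN.findall(md):
        if num:
            matched += int(num)
    return matched


def read_sam(path: str | Path, reference_lengths: dict | None = None) -> list:
    """Ingest primary mapped records from a SAM file as AlignmentRecords.

    Identity comes from the NM tag when present, else from MD; a record
    with neither raises :class:`SamRecordError` naming the read.  Unmapped,
    secondary and supplementary records are skipped (count logged).
    """
    import pysam

    records: list = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                skipped += 1
                continue
            cig = aln.cigartuples or []
            aligned = sum(ln for op, ln in cig if op in (0, 1, 7, 8))  # M, I, =, X
            m_bases = sum(ln for op, ln in cig if op in (0, 7, 8))
            ins = sum(ln for op, ln in cig if op == 1)
            dele = sum(ln for op, ln in cig if op == 2)
            read_len = aln.infer_read_length() or aligned
            if aln.has_tag("NM"):
                nm = int(aln.get_tag("NM"))
                matches = m_bases - (nm - ins - dele)
            elif aln.has_tag("MD"):
                matches = _matches_from_md(str(aln.get_tag("MD")))
            else:
                raise SamRecordError(
                    f"record {aln.query_name!r} has neither NM nor MD tag"
                )
            ref_name = aln.reference_name
            if reference_lengths is not None and ref_name in reference_lengths:
                if aln.reference_end > reference_lengths[ref_name]:
                    raise SamRecordError(
                        f"record {aln.query_name!r} extends past reference {ref_name}"
                    )
            strand = "-" if aln.is_reverse else "+"
            target = GenomicInterval(
                ref_name, aln.reference_start, aln.reference_end, strand
            )
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    target=target,
                    strand=strand,
                    matches=matches,
                    aligned_read_bases=aligned,
                    read_length=read_len,
                    tied_targets=((aln.reference_start, aln.reference_end),),
                )
            )
    if skipped:
        logger.info("read_sam: skipped %d unmapped/secondary/supplementary records", skipped)
    return records
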