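"""FASTA and BED readers/writers shared by every pipeline stage.

FASTA parsing is delegated to Biopython; this module adds the strict
alphabet/line diagnostics the pipeline contracts require.  BED3/BED6 is
handled directly so malformed lines can be reported by line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter

from .intervals import GenomicInterval, IntervalError, ReferenceSequence

FASTA_WRAP = 70


class FastaParseError(ValueError):
    pass


class BedParseError(ValueError):
    pass


def _locate_bad_line(path: Path, bad_chars: set[str]) -> int:
    """Best-effort line number of the first line holding an illegal character."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_chars:
                return lineno
    return 0


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a multi-record FASTA file, folding sequence to uppercase.

    Returns an empty list for an empty file.  A file whose first non-blank
    line is not a header, or a record holding characters outside
    {A,C,G,T,N}, raises :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header, got {line.strip()[:40]!r}"
                )
            break
        else:
            return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            lineno = _locate_bad_line(path, bad)
            raise FastaParseError(
                f"{path}: line {lineno}: illegal character(s) {sorted(bad)} in record {rec.id!r}"
            )
        records.append(ReferenceSequence(rec.id, seq))
    return records


def write_fasta(seqs: Iterable[ReferenceSequence], path: str | Path) -> None:
    """Write records wrapped at 70 columns; round-trips through read_fasta."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s.sequence), id=s.ref_id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(records)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open, per the BED standard)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except IntervalError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write BED, sorted by (ref_id, start).

    With ``names`` (parallel to ``intervals``) or any stranded interval a
    BED6 line is emitted, otherwise BED3.
    """
    if names is not None and len(names) != len(intervals):
        raise ValueError("names must parallel intervals")
    rows = sorted(
        zip(intervals, names if names is not None else [None] * len(intervals)),
        key=lambda r: (r[0].ref_id, r[0].start, r[0].end),
    )
    six = names is not None or any(iv.strand != "." for iv in intervals)
    with open(path, "w") as fh:
        for iv, name in rows:
            if six:
                fh.write(
                    f"{iv.ref_id}\t{iv.start}\t{iv.end}\t{name or '.'}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.ref_id}\t{iv.start}\t{iv.end}\n")
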