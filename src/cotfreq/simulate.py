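"""Synthetic repeat-structured genomes and simulated Cot-fractionated reads.

The generator stands in for a large, repeat-dense tick-like genome: i.i.d.
uniform background DNA, interspersed repeat families placed at known copy
numbers (each copy independently mutated at a per-family divergence rate),
and optionally an rDNA-like tandem array (18S-ITS1-5.8S-ITS2-28S plus an
intergenic spacer, repeated in cassettes).  Ground truth — placements, copy
numbers and genomic fractions — is retained so the downstream frequency
estimator can be validated against known values.

Cot fractionation is emulated by acceptance-rejection sampling: a candidate
fragment is kept with probability equal to the single-strand survival of the
family at its midpoint (background counts as copy number 1), so higher-Cot
samples are increasingly depleted of repetitive DNA, as in a hydroxyapatite
Cot filtration that retains the single-stranded fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, ReferenceSequence, reverse_complement
from .kinetics import ss_survival

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default 454-like read length model (bp)
DEFAULT_READ_LEN_MEAN = 250.0
DEFAULT_READ_LEN_SD = 50.0
READ_LEN_FLOOR = 50

#: default per-copy reassociation rate constant, L/(mol*s); see docs/methods.md
DEFAULT_K_BASE = 1e-6

_MAX_ATTEMPT_FACTOR = 1000


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RepeatFamilySpec:
    """An interspersed repeat family to plant in the genome."""

    family_id: str
    consensus: str
    copy_number: int
    divergence: float = 0.0  # per-base substitution probability
    indel_rate: float = 0.0  # per-base single-base indel probability (off by default)

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError(f"{self.family_id}: copy_number must be >= 1")
        if len(self.consensus) < 20:
            raise ValueError(f"{self.family_id}: consensus must be >= 20 bp")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError(f"{self.family_id}: divergence must be in [0, 0.3]")
        if self.indel_rate < 0:
            raise ValueError(f"{self.family_id}: negative indel_rate")


@dataclass(frozen=True)
class TandemArraySpec:
    """A tandem array of cassettes, each an ordered list of (part, length)."""

    array_id: str
    unit_parts: tuple  # ordered ((part_name, length_bp), ...)
    n_units: int

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError(f"{self.array_id}: n_units must be >= 1")
        if not self.unit_parts or any(length <= 0 for _, length in self.unit_parts):
            raise ValueError(f"{self.array_id}: every unit part needs a positive length")

    @property
    def unit_length(self) -> int:
        return sum(length for _, length in self.unit_parts)


@dataclass(frozen=True)
class FamilyTruth:
    copy_number: int
    element_length: int
    genomic_fraction: float


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    origin: GenomicInterval  # true genomic source (forward coordinates)
    strand: str
    family: str | None  # family at the fragment midpoint; None = unique DNA


@dataclass(frozen=True)
class CotFraction:
    """A simulated Cot-selected read set."""

    cot: float
    reads: tuple
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads != len(self.reads):
            raise ValueError("total_reads must equal len(reads)")


@dataclass
class SyntheticGenome:
    sequence: ReferenceSequence
    placements: list  # [(GenomicInterval, family_id), ...]
    truth_table: dict  # family_id -> FamilyTruth
    _codes: np.ndarray | None = field(default=None, repr=False)
    _copy_track: np.ndarray | None = field(default=None, repr=False)
    _family_track: np.ndarray | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return len(self.sequence.sequence)

    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = np.frombuffer(
                self.sequence.sequence.encode("ascii"), dtype=np.uint8
            )
        return self._codes

    def copy_number_track(self) -> np.ndarray:
        """Per-base copy number of the covering family (1 for unique DNA)."""
        if self._copy_track is None:
            track = np.ones(self.length, dtype=np.int64)
            for iv, fam in self.placements:
                track[iv.start : iv.end] = self.truth_table[fam].copy_number
            self._copy_track = track
        return self._copy_track

    def family_track(self) -> np.ndarray:
        """Per-base family index (-1 for unique DNA) into sorted family ids."""
        if self._family_track is None:
            fams = self.family_ids()
            idx = {f: i for i, f in enumerate(fams)}
            track = np.full(self.length, -1, dtype=np.int32)
            for iv, fam in self.placements:
                track[iv.start : iv.end] = idx[fam]
            self._family_track = track
        return self._family_track

    def family_ids(self) -> list:
        return sorted(self.truth_table)

    def unique_fraction(self) -> float:
        return 1.0 - sum(t.genomic_fraction for t in self.truth_table.values())


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, copy: np.ndarray, spec: RepeatFamilySpec) -> np.ndarray:
    out = copy.copy()
    if spec.divergence > 0:
        mask = rng.random(out.size) < spec.divergence
        if mask.any():
            # substitute to one of the three other bases
            codes = np.searchsorted(_BASES, out[mask])
            shift = rng.integers(1, 4, size=int(mask.sum()))
            out[mask] = _BASES[(codes + shift) % 4]
    if spec.indel_rate > 0:
        keep = rng.random(out.size) >= spec.indel_rate  # deletions
        out = out[keep]
        ins_mask = rng.random(out.size) < spec.indel_rate  # insertions after kept bases
        if ins_mask.any():
            pieces = []
            prev = 0
            for pos in np.nonzero(ins_mask)[0]:
                pieces.append(out[prev : pos + 1])
                pieces.append(_BASES[rng.integers(0, 4, size=1)])
                prev = pos + 1
            pieces.append(out[prev:])
            out = np.concatenate(pieces)
    return out


def _place(
    rng: np.random.Generator,
    occupied: np.ndarray,
    length: int,
    genome_length: int,
    label: str,
) -> int:
    """Uniform non-overlapping placement with bounded retries."""
    for _ in range(1000):
        start = int(rng.integers(0, genome_length - length + 1))
        if not occupied[start : start + length].any():
            occupied[start : start + length] = True
            return start
    raise SimulationError(
        f"could not place {label} ({length} bp) without overlap after 1000 tries; "
        "use a larger genome or fewer/shorter repeats"
    )


def build_genome(
    background_length: int,
    families: Sequence[RepeatFamilySpec] = (),
    arrays: Sequence[TandemArraySpec] = (),
    seed: int = 0,
    ref_id: str = "synthetic_genome",
) -> SyntheticGenome:
    """Build a genome of the given total length with planted repeats.

    Background is i.i.d. uniform A/C/G/T; each family copy is placed at a
    uniformly chosen non-overlapping position and independently mutated at
    the family divergence rate.  Deterministic given ``seed``.  Truth
    genomic fractions use the consensus length: copies * len / genome_len.
    """
    total_repeat = sum(len(f.consensus) * f.copy_number for f in families) + sum(
        a.unit_length * a.n_units for a in arrays
    )
    if total_repeat >= background_length:
        raise SimulationError(
            f"total repeat bp ({total_repeat}) must be below genome length ({background_length})"
        )
    rng = np.random.default_rng(seed)
    genome = _random_sequence(rng, background_length)
    occupied = np.zeros(background_length, dtype=bool)
    placements: list = []
    truth: dict = {}

    for arr in sorted(arrays, key=lambda a: (-a.unit_length * a.n_units, a.array_id)):
        cassette = np.concatenate(
            [_random_sequence(rng, length) for _, length in arr.unit_parts]
        )
        block = np.tile(cassette, arr.n_units)
        start = _place(rng, occupied, block.size, background_length, arr.array_id)
        genome[start : start + block.size] = block
        placements.append(
            (GenomicInterval(ref_id, start, start + block.size, "+"), arr.array_id)
        )
        truth[arr.array_id] = FamilyTruth(
            copy_number=arr.n_units,
            element_length=arr.unit_length,
            genomic_fraction=arr.unit_length * arr.n_units / background_length,
        )

    for fam in sorted(families, key=lambda f: (-len(f.consensus), f.family_id)):
        consensus = np.frombuffer(fam.consensus.upper().encode("ascii"), dtype=np.uint8)
        for _ in range(fam.copy_number):
            copy = _mutate(rng, consensus, fam)
            start = _place(rng, occupied, copy.size, background_length, fam.family_id)
            genome[start : start + copy.size] = copy
            placements.append(
                (GenomicInterval(ref_id, start, start + copy.size, "+"), fam.family_id)
            )
        truth[fam.family_id] = FamilyTruth(
            copy_number=fam.copy_number,
            element_length=len(fam.consensus),
            genomic_fraction=len(fam.consensus) * fam.copy_number / background_length,
        )

    placements.sort(key=lambda p: p[0].start)
    seq = ReferenceSequence(ref_id, genome.tobytes().decode("ascii"))
    return SyntheticGenome(sequence=seq, placements=placements, truth_table=truth)


def sample_bac(
    genome: SyntheticGenome, length: int, seed: int = 0, ref_id: str = "bac"
) -> tuple[ReferenceSequence, GenomicInterval]:
    """A contiguous BAC-like window at a seeded-uniform start position."""
    if length > genome.length:
        raise SimulationError(
            f"BAC length {length} exceeds genome length {genome.length}"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, genome.length - length + 1))
    source = GenomicInterval(genome.sequence.ref_id, start, start + length, "+")
    return ReferenceSequence(ref_id, genome.sequence.sequence[start : start + length]), source


def simulate_cot_fraction(
    genome: SyntheticGenome,
    cot: float,
    n_reads: int,
    read_len_mean: float = DEFAULT_READ_LEN_MEAN,
    read_len_sd: float = DEFAULT_READ_LEN_SD,
    k_base: float = DEFAULT_K_BASE,
    seed: int = 0,
    read_len_floor: int = READ_LEN_FLOOR,
) -> CotFraction:
    """Simulate one Cot-selected 454-like read set.

    Fragments are drawn with uniform starts and truncated-normal lengths and
    accepted with probability ``ss_survival(copy_number_at_midpoint, cot,
    k_base)``; exactly ``n_reads`` accepted fragments become reads, each on
    a uniformly chosen strand (reverse-complemented on ``-``).  At Cot 0
    every fragment is accepted, so read composition matches the genomic
    composition up to binomial sampling error.  Deterministic given seed.
    """
    if n_reads <= 0:
        raise ValueError(f"n_reads must be positive, got {n_reads}")
    if read_len_mean < 50:
        raise ValueError(f"read_len_mean must be >= 50, got {read_len_mean}")
    if read_len_sd < 0 or read_len_floor < 1:
        raise ValueError("read length parameters must be positive")
    if cot < 0:
        raise ValueError(f"negative Cot value {cot}")

    rng = np.random.default_rng(seed)
    glen = genome.length
    track = genome.copy_number_track()
    fam_track = genome.family_track()
    fam_ids = genome.family_ids()
    seq = genome.sequence.sequence

    accepted: list[tuple[int, int, bool]] = []  # (start, length, reverse)
    attempts = 0
    max_attempts = _MAX_ATTEMPT_FACTOR * n_reads
    batch = max(4 * n_reads, 1000)
    while len(accepted) < n_reads:
        if attempts >= max_attempts:
            raise SimulationError(
                f"acceptance-rejection cap reached ({max_attempts} attempts) at Cot {cot}"
            )
        b = min(batch, max_attempts - attempts)
        attempts += b
        lengths = np.rint(rng.normal(read_len_mean, read_len_sd, size=b)).astype(np.int64)
        lengths = np.clip(lengths, read_len_floor, glen)
        starts = rng.integers(0, glen - lengths + 1)
        strands = rng.random(b) < 0.5  # True = reverse
        mids = starts + lengths // 2
        if cot == 0:
            keep = np.ones(b, dtype=bool)
        else:
            surv = 1.0 / (1.0 + k_base * track[mids] * cot)
            keep = rng.random(b) < surv
        for s, ln, rev in zip(starts[keep], lengths[keep], strands[keep]):
            accepted.append((int(s), int(ln), bool(rev)))
            if len(accepted) == n_reads:
                break

    reads = []
    for i, (start, ln, rev) in enumerate(accepted):
        end = start + ln
        fragment = seq[start:end]
        strand = "-" if rev else "+"
        if rev:
            fragment = reverse_complement(fragment)
        fam_idx = int(fam_track[start + ln // 2])
        fam = fam_ids[fam_idx] if fam_idx >= 0 else None
        read_id = (
            f"r{i:07d}|{genome.sequence.ref_id}:{start}-{end}|{strand}|{fam or 'unique'}"
        )
        reads.append(
            SimulatedRead(
                read_id=read_id,
                sequence=fragment,
                origin=GenomicInterval(genome.sequence.ref_id, start, end, strand),
                strand=strand,
                family=fam,
            )
        )
    return CotFraction(cot=cot, reads=tuple(reads), total_reads=n_reads)


def write_reads(fraction: CotFraction, path: str | Path, format: str = "fasta") -> None:
    """Write reads as FASTA or FASTQ (constant placeholder qualities).

    Read ids encode the true origin interval so downstream truth checks can
    recover the source of every read.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown read format {format!r}")
    with open(path, "w") as fh:
        for read in fraction.reads:
            if format == "fasta":
                fh.write(f">{read.read_id}\n{read.sequence}\n")
            else:
                fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def read_truth_table_tsv(path: str | Path) -> dict:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {
        row.family_id: FamilyTruth(
            int(row.copy_number), int(row.element_length), float(row.genomic_fraction)
        )
        for row in df.itertuples()
    }


def write_truth_table_tsv(genome: SyntheticGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tcopy_number\telement_length\tgenomic_fraction\n")
        for fam in genome.family_ids():
            t = genome.truth_table[fam]
            fh.write(
                f"{fam}\t{t.copy_number}\t{t.element_length}\t{t.genomic_fraction:.6g}\n"
            )
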