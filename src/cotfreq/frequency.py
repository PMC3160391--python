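"""Genome-wide element frequency and copy number from Cot-fraction read sets.

The headline computation: for each Cot-selected sample count the distinct
mapped reads whose placement overlaps the element, divide by the total
sequenced reads of that sample, extrapolate the per-sample fractions back
to Cot zero, and convert the Cot-zero fraction f0 into genome mass
(f0 * G bp) and copy number (floor(f0 * G / L)).  The floor matches the
"at least N copies" reading of such estimates: the chain systematically
loses reads (strict mapping thresholds, reads extending past element
boundaries, residual reassociation depletion), so it is a lower bound.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .intervals import GenomicInterval, overlap_length
from .kinetics import FractionPoint, extrapolate_to_cot_zero

#: default genome size (bp) — haploid genome estimate for the cattle tick
DEFAULT_GENOME_SIZE = 7.1e9

_FLOOR_SNAP = 1e-6  # absolute guard against float error just under an integer


class FrequencyError(ValueError):
    pass


@dataclass(frozen=True)
class FractionCount:
    """Element read counts for one Cot-selected sample."""

    cot: float
    element_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise FrequencyError("total_reads must be positive")
        if not 0 <= self.element_reads <= self.total_reads:
            raise FrequencyError("element_reads must be in [0, total_reads]")

    @property
    def fraction(self) -> float:
        return self.element_reads / self.total_reads

    def as_point(self) -> FractionPoint:
        return FractionPoint(self.cot, self.fraction)


def element_read_fraction(
    element: GenomicInterval, alignments: Sequence, total_reads: int
) -> float:
    """Fraction of all sequenced reads overlapping the element.

    The numerator counts distinct reads with *any* tied-best placement
    overlapping the element by at least 1 bp — multi-mapping reads from a
    repeat family are not lost to tie-breaking.  The denominator is the
    total sequenced read count of the sample, not the mapped count.
    """
    if total_reads <= 0:
        raise FrequencyError("total_reads must be positive")
    seen = set()
    for rec in alignments:
        if rec.read_id in seen:
            continue
        placements = rec.tied_targets or ((rec.target.start, rec.target.end),)
        for s, e in placements:
            iv = GenomicInterval(element.ref_id, s, e)
            if overlap_length(iv, element) > 0:
                seen.add(rec.read_id)
                break
    return len(seen) / total_reads


def copies_from_fraction(f0: float, genome_size: float, element_length: int) -> int:
    """floor(f0 * G / L), with a tiny snap guard against float error."""
    if not 0.0 <= f0 <= 1.0:
        raise FrequencyError(f"fraction {f0} outside [0, 1]")
    if genome_size <= 0 or element_length <= 0:
        raise FrequencyError("genome_size and element_length must be positive")
    c = f0 * genome_size / element_length
    nearest = round(c)
    if abs(c - nearest) < _FLOOR_SNAP:
        return int(nearest)
    return int(math.floor(c))


@dataclass(frozen=True)
class ElementFrequencyEstimate:
    element: GenomicInterval | None
    element_length: int
    per_fraction: tuple  # FractionCount or FractionPoint entries
    f0: float
    mode: str
    genome_size: float

    @property
    def genome_mass(self) -> float:
        """Estimated bp of the genome occupied by the element family."""
        return self.f0 * self.genome_size

    @property
    def copy_number(self) -> int:
        return copies_from_fraction(self.f0, self.genome_size, self.element_length)


def estimate_copies(
    points: Sequence,
    genome_size: float = DEFAULT_GENOME_SIZE,
    element_length: int | None = None,
    mode: str = "linear",
    element: GenomicInterval | None = None,
) -> ElementFrequencyEstimate:
    """Extrapolate per-Cot fractions to Cot zero and scale to the genome.

    ``points`` are FractionCount/FractionPoint entries (or (cot, fraction)
    pairs).  ``element_length`` defaults to the closed-interval length of
    ``element`` when an annotation is supplied.
    """
    if element_length is None:
        if element is None:
            raise FrequencyError("need element_length or an element annotation")
        element_length = element.length
    if element_length <= 0 or genome_size <= 0:
        raise FrequencyError("genome_size and element_length must be positive")
    pts = [p.as_point() if isinstance(p, FractionCount) else p for p in points]
    f0 = extrapolate_to_cot_zero(pts, mode=mode)
    return ElementFrequencyEstimate(
        element=element,
        element_length=int(element_length),
        per_fraction=tuple(points),
        f0=f0,
        mode=mode,
        genome_size=float(genome_size),
    )


def config_hash(metadata: dict) -> str:
    """Stable hash of a run configuration (machine-independent)."""
    canon = json.dumps(metadata, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def frequency_report(
    estimates: Sequence[ElementFrequencyEstimate],
    run_metadata: dict | None = None,
    json_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> dict:
    """Serialisable report of one or more estimates; stable field order."""
    if not estimates:
        raise FrequencyError("need at least one estimate")
    run_metadata = run_metadata or {}
    report = {
        "estimates": [],
        "config": run_metadata,
        "config_hash": config_hash(run_metadata),
    }
    for est in estimates:
        per_fraction = []
        for p in est.per_fraction:
            if isinstance(p, FractionCount):
                per_fraction.append(
                    {
                        "cot": p.cot,
                        "element_reads": p.element_reads,
                        "total_reads": p.total_reads,
                        "fraction": p.fraction,
                    }
                )
            else:
                pt = p if isinstance(p, FractionPoint) else FractionPoint(*p)
                per_fraction.append({"cot": pt.cot, "fraction": pt.fraction})
        report["estimates"].append(
            {
                "element": (
                    {
                        "ref_id": est.element.ref_id,
                        "start": est.element.start,
                        "end": est.element.end,
                    }
                    if est.element
                    else None
                ),
                "element_length": est.element_length,
                "per_fraction": per_fraction,
                "f0": est.f0,
                "mode": est.mode,
                "genome_size": est.genome_size,
                "genome_mass": est.genome_mass,
                "copy_number": est.copy_number,
            }
        )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write(
                "element\telement_length\tf0\tmode\tgenome_size\tgenome_mass\tcopy_number\n"
            )
            for est in estimates:
                name = (
                    f"{est.element.ref_id}:{est.element.start}-{est.element.end}"
                    if est.element
                    else "."
                )
                fh.write(
                    f"{name}\t{est.element_length}\t{est.f0:.6g}\t{est.mode}\t"
                    f"{est.genome_size:.6g}\t{est.genome_mass:.6g}\t{est.copy_number}\n"
                )
    return report


def load_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
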