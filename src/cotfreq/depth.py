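"""Windowed read-depth statistics over a reference.

Two normalisations are computed, mirroring the two formulas used for
Cot-read heatmaps over BAC sequence:

* count-based: reads assigned to the 100 bp window containing their start,
  normalised by a read-count denominator ("read number per 100 bp window"
  over a total read count).  Because the total can be read either as reads
  mapped to the reference or as all sequenced reads, both denominators are
  computed and reported side by side.
* depth-based: per-window mean base depth over global mean base depth,
  ``(sum bp depth / window size) / (sum total bp depth / reference length)``.

The log2 of the depth-based track (with a small pseudocount for empty
windows) is the heatmap value, clipped to the display range [0, 10].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

LOG2_PSEUDOCOUNT = 2.0 ** -10
LOG2_DISPLAY_MAX = 10.0


class DepthError(ValueError):
    pass


def _window_lengths(reference_length: int, window: int) -> np.ndarray:
    n = -(-reference_length // window)  # ceil; final partial window kept
    lengths = np.full(n, window, dtype=np.int64)
    if reference_length % window:
        lengths[-1] = reference_length % window
    return lengths


def _check_alignments(alignments: Sequence, reference_length: int) -> None:
    for a in alignments:
        if a.target.start >= reference_length or a.target.end > reference_length:
            raise DepthError(
                f"alignment {a.read_id!r} [{a.target.start}, {a.target.end}) "
                f"extends beyond reference of length {reference_length}"
            )


def window_counts(
    alignments: Sequence, reference_length: int, window: int = 100
) -> np.ndarray:
    """Per-window primary-read counts; each read counted in the window
    containing its target start.  The counts sum to len(alignments)."""
    if window < 1:
        raise DepthError(f"window must be >= 1, got {window}")
    _check_alignments(alignments, reference_length)
    n = _window_lengths(reference_length, window).size
    if not alignments:
        return np.zeros(n, dtype=np.int64)
    starts = np.array([a.target.start for a in alignments], dtype=np.int64)
    return np.bincount(starts // window, minlength=n).astype(np.int64)


def base_depth(alignments: Sequence, reference_length: int) -> np.ndarray:
    """Per-position aligned-base depth."""
    _check_alignments(alignments, reference_length)
    diff = np.zeros(reference_length + 1, dtype=np.int64)
    for a in alignments:
        diff[a.target.start] += 1
        diff[a.target.end] -= 1
    return np.cumsum(diff[:-1])


def normalized_depth(
    alignments: Sequence, reference_length: int, window: int = 100
) -> np.ndarray:
    """Per-window mean base depth over global mean base depth.

    A uniformly covered reference gives 1.0 in every full window; the final
    partial window is normalised by its actual length.
    """
    if window < 1:
        raise DepthError(f"window must be >= 1, got {window}")
    depth = base_depth(alignments, reference_length)
    total = int(depth.sum())
    if total == 0:
        raise DepthError(
            "zero total aligned bp: no reads mapped; check the mapping stage"
        )
    lengths = _window_lengths(reference_length, window)
    edges = np.concatenate(([0], np.cumsum(lengths)))[:-1]
    win_sum = np.add.reduceat(depth, edges)
    return (win_sum / lengths) / (total / reference_length)


def log2_heatmap(
    norm_depth: np.ndarray, pseudocount: float = LOG2_PSEUDOCOUNT
) -> tuple[np.ndarray, np.ndarray]:
    """(raw, clipped) log2 heatmap values.

    raw = log2(value + pseudocount); clipped rescales nothing, it simply
    clips raw into the display range [0, 10] used for heatmap rendering.
    """
    values = np.asarray(norm_depth, dtype=float)
    if (values < 0).any():
        raise DepthError("normalised depth values must be non-negative")
    raw = np.log2(values + pseudocount)
    return raw, np.clip(raw, 0.0, LOG2_DISPLAY_MAX)


def coverage_fraction(alignments: Sequence, reference_length: int) -> float:
    """Fraction of reference positions covered by at least one aligned base."""
    if reference_length <= 0:
        raise DepthError("reference_length must be positive")
    if not alignments:
        return 0.0
    return float((base_depth(alignments, reference_length) > 0).mean())


@dataclass
class DepthProfile:
    """All windowed tracks for one reference."""

    ref_id: str
    reference_length: int
    window: int
    read_counts: np.ndarray
    bp_depth: np.ndarray  # per-window summed aligned base depth
    norm_count_mapped: np.ndarray  # counts / reads mapped to this reference
    norm_count_total: np.ndarray | None  # counts / total sequenced reads
    norm_depth: np.ndarray
    log2_raw: np.ndarray
    log2_clipped: np.ndarray
    coverage: float

    @classmethod
    def from_alignments(
        cls,
        alignments: Sequence,
        ref_id: str,
        reference_length: int,
        window: int = 100,
        total_sequenced_reads: int | None = None,
    ) -> "DepthProfile":
        counts = window_counts(alignments, reference_length, window)
        depth = base_depth(alignments, reference_length)
        lengths = _window_lengths(reference_length, window)
        edges = np.concatenate(([0], np.cumsum(lengths)))[:-1]
        win_sum = np.add.reduceat(depth, edges) if reference_length else np.zeros(0)
        nd = normalized_depth(alignments, reference_length, window)
        raw, clipped = log2_heatmap(nd)
        n_mapped = len(alignments)
        return cls(
            ref_id=ref_id,
            reference_length=reference_length,
            window=window,
            read_counts=counts,
            bp_depth=win_sum.astype(np.int64),
            norm_count_mapped=counts / n_mapped,
            norm_count_total=(
                counts / total_sequenced_reads if total_sequenced_reads else None
            ),
            norm_depth=nd,
            log2_raw=raw,
            log2_clipped=clipped,
            coverage=coverage_fraction(alignments, reference_length),
        )

    def window_starts(self) -> np.ndarray:
        return np.arange(self.read_counts.size, dtype=np.int64) * self.window

    def window_ends(self) -> np.ndarray:
        ends = self.window_starts() + self.window
        ends[-1] = self.reference_length
        return ends

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "ref_id": self.ref_id,
                "window_start": self.window_starts(),
                "window_end": self.window_ends(),
                "read_count": self.read_counts,
                "bp_depth": self.bp_depth,
                "norm_count_mapped": self.norm_count_mapped,
                "norm_depth": self.norm_depth,
                "log2_raw": self.log2_raw,
                "log2_clipped": self.log2_clipped,
            }
        )
        if self.norm_count_total is not None:
            df.insert(6, "norm_count_total", self.norm_count_total)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_bedgraph(self, path: str | Path, track: str = "norm_depth") -> None:
        values = getattr(self, track)
        starts, ends = self.window_starts(), self.window_ends()
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{self.ref_id}:{track}"\n')
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{self.ref_id}\t{s}\t{e}\t{v:.6g}\n")
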