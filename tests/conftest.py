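import numpy as np
import pytest

from cotfreq.intervals import GenomicInterval
from cotfreq.mapping import AlignmentRecord


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mk_aln(start, end, read_id="r", ref_id="ref", strand="+", tied=None):
    """Minimal perfect-identity alignment record for depth/frequency tests."""
    return AlignmentRecord(
        read_id=read_id,
        target=GenomicInterval(ref_id, start, end, strand),
        strand=strand,
        matches=end - start,
        aligned_read_bases=end - start,
        read_length=end - start,
        tied_targets=tuple(tied) if tied else ((start, end),),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
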