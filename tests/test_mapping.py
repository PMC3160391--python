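"""Seed-and-extend mapper: contracts, oracle equivalence, SAM ingestion."""

import numpy as np
import pytest

from cotfreq.intervals import GenomicInterval, ReferenceSequence, reverse_complement
from cotfreq.mapping import (
    MappingConfig,
    MappingError,
    SamRecordError,
    UNMAPPED_NO_PLACEMENT,
    UNMAPPED_TOO_SHORT,
    alignments_from_tsv,
    find_element_copies,
    map_reads,
    read_sam,
)

from conftest import random_seq


def brute_force_best(ref: str, read: str, min_identity: float, min_coverage: float):
    """Independent all-offset scan; returns (matches, start, end, strand) of the
    best qualifying placement (ties: lowest start, + before -), or None."""
    L, rlen = len(ref), len(read)
    min_aligned = int(np.ceil(min_coverage * rlen - 1e-9))
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    best = None
    for strand in "+-":
        seq = read if strand == "+" else reverse_complement(read)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for start in range(-(rlen - min_aligned), L - min_aligned + 1):
            lo, hi = max(0, start), min(L, start + rlen)
            aligned = hi - lo
            if aligned < min_aligned:
                continue
            a = arr[lo - start : hi - start]
            b = ref_arr[lo:hi]
            matches = int(((a == b) & (a != ord("N")) & (b != ord("N"))).sum())
            if matches < min_identity * aligned - 1e-9:
                continue
            key = (-matches, lo, strand == "-")
            if best is None or key < best[0]:
                best = (key, (matches, lo, hi, strand))
    return None if best is None else best[1]


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(42)
    return ReferenceSequence("ref", random_seq(rng, 2000))


class TestMapReads:
    def test_exact_substring(self, reference):
        read = reference.sequence[100:300]
        res = map_reads([("q", read)], reference)
        (rec,) = res.records
        assert (rec.target.start, rec.target.end) == (100, 300)
        assert rec.identity == 1.0 and rec.read_coverage == 1.0
        assert rec.strand == "+"

    def test_single_mismatch_fails_strict_identity(self, reference):
        read = list(reference.sequence[100:300])
        read[50] = {"A": "C"}.get(read[50], "A")
        read = "".join(read)
        res = map_reads([("q", read)], reference)
        assert res.records == []
        assert res.unmapped == [("q", UNMAPPED_NO_PLACEMENT)]
        # relaxed identity maps it at the same locus
        res2 = map_reads([("q", read)], reference, MappingConfig(min_identity=0.95))
        assert res2.records[0].target.start == 100

    def test_reverse_complement_maps_minus_strand(self, reference):
        read = reverse_complement(reference.sequence[400:600])
        (rec,) = map_reads([("q", read)], reference).records
        assert (rec.target.start, rec.target.end, rec.strand) == (400, 600, "-")

    def test_read_shorter_than_seed_recorded_not_raised(self, reference):
        res = map_reads([("tiny", "ACGTACGT")], reference)
        assert res.unmapped == [("tiny", UNMAPPED_TOO_SHORT)]

    def test_repeat_read_reports_tied_placements(self, rng):
        unit = random_seq(rng, 300)
        bg = random_seq(rng, 2000)
        ref = ReferenceSequence("r", bg[:500] + unit + bg[500:1000] + unit + bg[1000:])
        read = unit[50:250]
        (rec,) = map_reads([("q", read)], ref).records
        assert len(rec.tied_targets) == 2
        assert rec.target.start == min(s for s, _ in rec.tied_targets)

    def test_determinism_byte_identical_tables(self, reference, rng, tmp_path):
        reads = [(f"q{i}", random_seq(rng, 120)) for i in range(20)]
        reads += [(f"p{i}", reference.sequence[i * 37 : i * 37 + 150]) for i in range(20)]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        map_reads(reads, reference, seed=1).to_tsv(p1)
        map_reads(reads, reference, seed=2).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_threshold_monotonicity(self, reference, rng):
        reads = []
        for i in range(60):
            start = int(rng.integers(0, 1800))
            read = list(reference.sequence[start : start + 150])
            for pos in rng.integers(0, 150, size=int(rng.integers(0, 4))):
                read[pos] = "ACGT"[(("ACGT".index(read[pos])) + 1) % 4]
            reads.append((f"q{i}", "".join(read)))
        strict = map_reads(reads, reference, MappingConfig(1.0, 0.9))
        loose = map_reads(reads, reference, MappingConfig(0.95, 0.8))
        strict_ids = {r.read_id for r in strict.records}
        loose_ids = {r.read_id for r in loose.records}
        assert strict_ids <= loose_ids

    @pytest.mark.parametrize("min_identity,min_coverage", [(1.0, 0.9), (0.95, 0.8)])
    def test_matches_brute_force_scan(self, min_identity, min_coverage):
        # classification and placement start must equal an exhaustive
        # all-offset scan on small references
        rng = np.random.default_rng(77)
        cfg = MappingConfig(min_identity, min_coverage)
        for trial in range(40):
            ref = ReferenceSequence("r", random_seq(rng, 1200))
            kind = trial % 4
            if kind == 0:  # exact
                s = int(rng.integers(0, 1000))
                read = ref.sequence[s : s + 180]
            elif kind == 1:  # a few substitutions
                s = int(rng.integers(0, 1000))
                read = list(ref.sequence[s : s + 180])
                for pos in rng.integers(0, 180, size=3):
                    read[pos] = "ACGT"[("ACGT".index(read[pos]) + 1) % 4]
                read = "".join(read)
            elif kind == 2:  # reverse strand
                s = int(rng.integers(0, 1000))
                read = reverse_complement(ref.sequence[s : s + 150])
            else:  # unrelated sequence
                read = random_seq(rng, 160)
            got = map_reads([("q", read)], ref, cfg)
            want = brute_force_best(ref.sequence, read, min_identity, min_coverage)
            if want is None:
                assert got.records == []
            else:
                assert got.records, f"mapper missed placement {want}"
                rec = got.records[0]
                assert (rec.matches, rec.target.start, rec.target.end, rec.strand) == want

    def test_empty_inputs_rejected(self, reference):
        with pytest.raises(MappingError):
            map_reads([], reference)


class TestFindElementCopies:
    def test_verbatim_probe_found_once(self, rng):
        probe = random_seq(rng, 195)
        bg = random_seq(rng, 3000)
        ref = ReferenceSequence("r", bg[:1000] + probe + bg[1000:])
        (hit,) = find_element_copies(ref, probe)
        assert (hit.start, hit.end) == (1000, 1195)

    def test_diverged_plants_found_at_default_thresholds(self, rng):
        probe = random_seq(rng, 195)
        plants, chunks, cursor = [], [], 0
        bg = random_seq(rng, 4000)
        positions = [500, 1800, 3200]
        seq = ""
        prev = 0
        for p in positions:
            seq += bg[prev:p]
            copy = list(probe)
            for pos in rng.choice(195, size=9, replace=False):  # ~5% divergence
                copy[pos] = "ACGT"[("ACGT".index(copy[pos]) + 1) % 4]
            plants.append(len(seq))
            seq += "".join(copy)
            prev = p
        seq += bg[prev:]
        ref = ReferenceSequence("r", seq)
        hits = find_element_copies(ref, probe, min_identity=0.84, min_coverage=0.69)
        assert [h.start for h in hits] == plants

        # tightening thresholds to exact-match drops the diverged plants
        exact = find_element_copies(ref, probe, min_identity=1.0, min_coverage=1.0)
        assert exact == []

    def test_empty_probe_rejected(self, reference):
        with pytest.raises(MappingError):
            find_element_copies(reference, "")


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:ref\tLN:2000\n"


class TestReadSam:
    def write(self, tmp_path, body):
        path = tmp_path / "in.sam"
        path.write_text(SAM_HEADER + body)
        return path

    def test_nm_and_softclip_arithmetic(self, tmp_path, reference):
        seq100 = reference.sequence[:100]
        body = (
            f"r1\t0\tref\t1\t60\t100M\t*\t0\t0\t{seq100}\t*\tNM:i:0\n"
            f"r2\t0\tref\t1\t60\t90M10S\t*\t0\t0\t{seq100}\t*\tNM:i:0\n"
            f"r3\t0\tref\t1\t60\t100M\t*\t0\t0\t{seq100}\t*\tNM:i:5\n"
        )
        recs = read_sam(self.write(tmp_path, body), {"ref": 2000})
        by_id = {r.read_id: r for r in recs}
        assert by_id["r1"].identity == 1.0 and by_id["r1"].read_coverage == 1.0
        assert by_id["r2"].read_coverage == pytest.approx(0.9)
        assert by_id["r2"].identity == 1.0
        assert by_id["r3"].identity == pytest.approx(0.95)

    def test_md_fallback_and_missing_tags(self, tmp_path, reference):
        seq100 = reference.sequence[:100]
        body = f"r1\t0\tref\t1\t60\t100M\t*\t0\t0\t{seq100}\t*\tMD:Z:40A59\n"
        (rec,) = read_sam(self.write(tmp_path, body), {"ref": 2000})
        assert rec.identity == pytest.approx(0.99)

        body = f"r1\t0\tref\t1\t60\t100M\t*\t0\t0\t{seq100}\t*\n"
        with pytest.raises(SamRecordError, match="r1"):
            read_sam(self.write(tmp_path, body), {"ref": 2000})

    def test_unmapped_and_secondary_skipped(self, tmp_path, reference):
        seq100 = reference.sequence[:100]
        body = (
            f"r1\t4\t*\t0\t0\t*\t*\t0\t0\t{seq100}\t*\n"
            f"r2\t256\tref\t1\t60\t100M\t*\t0\t0\t{seq100}\t*\tNM:i:0\n"
            f"r3\t16\tref\t1\t60\t100M\t*\t0\t0\t{seq100}\t*\tNM:i:0\n"
        )
        recs = read_sam(self.write(tmp_path, body), {"ref": 2000})
        assert [r.read_id for r in recs] == ["r3"]
        assert recs[0].strand == "-"


def test_alignment_table_roundtrip(reference, tmp_path, rng):
    reads = [(f"p{i}", reference.sequence[i * 100 : i * 100 + 150]) for i in range(10)]
    res = map_reads(reads, reference)
    path = tmp_path / "aln.tsv"
    res.to_tsv(path)
    back = alignments_from_tsv(path)
    assert back == res.records
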