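"""Synthetic genome construction and Cot-fraction read simulation."""

import math

import numpy as np
import pytest

from cotfreq.intervals import overlap_length
from cotfreq.simulate import (
    CotFraction,
    RepeatFamilySpec,
    SimulationError,
    TandemArraySpec,
    build_genome,
    sample_bac,
    simulate_cot_fraction,
    write_reads,
)

from conftest import random_seq


@pytest.fixture(scope="module")
def sine_family():
    rng = np.random.default_rng(101)
    return RepeatFamilySpec("sine1", random_seq(rng, 195), copy_number=500)


@pytest.fixture(scope="module")
def sine_genome(sine_family):
    """2 Mb genome carrying a 195 bp SINE-like family at 500 copies."""
    return build_genome(2_000_000, [sine_family], seed=11)


class TestBuildGenome:
    def test_zero_divergence_copies_equal_consensus(self, rng):
        fam = RepeatFamilySpec("f", random_seq(rng, 60), copy_number=3)
        g = build_genome(10_000, [fam], seed=3)
        assert len(g.placements) == 3
        for iv, fam_id in g.placements:
            assert fam_id == "f"
            assert g.sequence.sequence[iv.start : iv.end] == fam.consensus

    def test_deterministic(self, rng):
        fam = RepeatFamilySpec("f", random_seq(rng, 60), copy_number=5, divergence=0.1)
        a = build_genome(20_000, [fam], seed=7)
        b = build_genome(20_000, [fam], seed=7)
        assert a.sequence == b.sequence
        assert a.placements == b.placements

    def test_truth_fraction_arithmetic(self, sine_genome):
        t = sine_genome.truth_table["sine1"]
        assert t.genomic_fraction == pytest.approx(500 * 195 / 2e6)
        assert t.genomic_fraction == pytest.approx(0.04875)

    def test_fraction_conservation(self, sine_genome):
        total = sum(t.genomic_fraction for t in sine_genome.truth_table.values())
        assert total + sine_genome.unique_fraction() == pytest.approx(1.0, abs=1e-9)
        placed = sum(iv.length for iv, _ in sine_genome.placements)
        assert placed / sine_genome.length == pytest.approx(total, abs=1e-9)

    def test_placements_disjoint(self, sine_genome):
        ivs = sorted((iv for iv, _ in sine_genome.placements), key=lambda i: i.start)
        assert all(
            overlap_length(a, b) == 0 for a, b in zip(ivs, ivs[1:])
        )

    def test_tandem_array_truth(self, rng):
        arr = TandemArraySpec(
            "rdna",
            unit_parts=(("18S", 300), ("ITS1", 50), ("5.8S", 40), ("ITS2", 60), ("28S", 500), ("IGS", 250)),
            n_units=3,
        )
        g = build_genome(50_000, [], [arr], seed=5)
        t = g.truth_table["rdna"]
        assert t.element_length == 1200
        assert t.copy_number == 3
        (iv, _), = g.placements
        assert iv.length == 3600
        unit = g.sequence.sequence[iv.start : iv.start + 1200]
        assert g.sequence.sequence[iv.start : iv.end] == unit * 3

    def test_overfull_genome_rejected(self, rng):
        fam = RepeatFamilySpec("f", random_seq(rng, 100), copy_number=200)
        with pytest.raises(SimulationError):
            build_genome(10_000, [fam], seed=1)


class TestSampleBac:
    def test_whole_genome(self, sine_genome):
        bac, src = sample_bac(sine_genome, sine_genome.length, seed=1)
        assert bac.sequence == sine_genome.sequence.sequence
        assert (src.start, src.end) == (0, sine_genome.length)

    def test_window_and_determinism(self, sine_genome):
        bac1, src1 = sample_bac(sine_genome, 135_000, seed=4)
        bac2, src2 = sample_bac(sine_genome, 135_000, seed=4)
        assert src1 == src2 and bac1 == bac2
        assert src1.length == 135_000
        assert bac1.sequence == sine_genome.sequence.sequence[src1.start : src1.end]

    def test_too_long_rejected(self, sine_genome):
        with pytest.raises(SimulationError):
            sample_bac(sine_genome, sine_genome.length + 1, seed=0)


class TestSimulateCotFraction:
    def test_deterministic(self, sine_genome):
        a = simulate_cot_fraction(sine_genome, 69.56, 500, seed=9)
        b = simulate_cot_fraction(sine_genome, 69.56, 500, seed=9)
        assert a == b

    def test_read_ids_encode_origin(self, sine_genome):
        fr = simulate_cot_fraction(sine_genome, 0.0, 50, seed=2)
        for read in fr.reads:
            _, span, strand, _ = read.read_id.split("|")
            start, end = map(int, span.split(":")[1].split("-"))
            assert (start, end, strand) == (read.origin.start, read.origin.end, read.strand)
            assert len(read.sequence) == end - start

    def test_cot_zero_composition_matches_truth(self, sine_genome):
        # with no reassociation the read origins are a binomial draw from
        # the genomic composition: agree within 3 SD at n = 50,000
        n = 50_000
        fr = simulate_cot_fraction(sine_genome, 0.0, n, seed=13)
        f_true = sine_genome.truth_table["sine1"].genomic_fraction
        f_hat = sum(1 for r in fr.reads if r.family == "sine1") / n
        sd = math.sqrt(f_true * (1 - f_true) / n)
        assert abs(f_hat - f_true) <= 3 * sd

    def test_monotone_depletion_across_cots(self, sine_genome):
        # element read fraction should not increase with Cot (k_base default)
        n = 20_000
        fracs = []
        for i, cot in enumerate([0.0, 69.56, 695.6]):
            fr = simulate_cot_fraction(sine_genome, cot, n, seed=100 + i)
            fracs.append(sum(1 for r in fr.reads if r.family == "sine1") / n)
        f_true = sine_genome.truth_table["sine1"].genomic_fraction
        tol = 3 * math.sqrt(f_true * (1 - f_true) / n)
        assert fracs[1] <= fracs[0] + tol
        assert fracs[2] <= fracs[1] + tol
        assert fracs[2] < fracs[0]  # clear depletion at the high Cot

    def test_strands_both_present_and_revcomp_consistent(self, sine_genome):
        from cotfreq.intervals import reverse_complement

        fr = simulate_cot_fraction(sine_genome, 0.0, 200, seed=5)
        strands = {r.strand for r in fr.reads}
        assert strands == {"+", "-"}
        for r in fr.reads:
            genomic = sine_genome.sequence.sequence[r.origin.start : r.origin.end]
            expect = reverse_complement(genomic) if r.strand == "-" else genomic
            assert r.sequence == expect

    def test_rejection_cap_raises(self, sine_genome):
        # survival ~1e-9 everywhere: the bounded-attempts guard must trip
        with pytest.raises(SimulationError, match="cap"):
            simulate_cot_fraction(sine_genome, 1e9, 10, k_base=1.0, seed=1)

    def test_parameter_validation(self, sine_genome):
        with pytest.raises(ValueError):
            simulate_cot_fraction(sine_genome, 1.0, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_cot_fraction(sine_genome, 1.0, 10, read_len_mean=10, seed=1)


class TestWriteReads:
    def test_fasta_fastq_roundtrip_counts(self, sine_genome, tmp_path):
        fr = simulate_cot_fraction(sine_genome, 0.0, 25, seed=3)
        fa, fq = tmp_path / "r.fasta", tmp_path / "r.fastq"
        write_reads(fr, fa, "fasta")
        write_reads(fr, fq, "fastq")
        assert sum(1 for l in open(fa) if l.startswith(">")) == 25
        assert sum(1 for l in open(fq) if l.startswith("@r")) == 25

    def test_empty_fraction_valid_file(self, tmp_path):
        fr = CotFraction(cot=0.0, reads=(), total_reads=0)
        path = tmp_path / "empty.fasta"
        write_reads(fr, path, "fasta")
        assert path.read_text() == ""

    def test_unknown_format_rejected(self, tmp_path):
        fr = CotFraction(cot=0.0, reads=(), total_reads=0)
        with pytest.raises(ValueError):
            write_reads(fr, tmp_path / "x", "bam")


def test_family_spec_validation():
    with pytest.raises(ValueError):
        RepeatFamilySpec("f", "ACGT" * 5, copy_number=0)
    with pytest.raises(ValueError):
        RepeatFamilySpec("f", "ACGTACGTACGTACGT", copy_number=1)  # < 20 bp
    with pytest.raises(ValueError):
        RepeatFamilySpec("f", "ACGT" * 5, copy_number=1, divergence=0.5)
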