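# Methods

## The estimation problem

Large arthropod genomes — the cattle-tick genome at an estimated 7.1 Gb is
the motivating case — are dominated by repetitive DNA, and in the absence
of an assembled reference the genome-wide abundance of a repeat element
cannot be counted directly.  Cot filtration offers an indirect route.
Sheared, denatured genomic DNA reassociates with second-order kinetics:
the more copies a sequence family has, the faster its strands find
partners.  If the still-single-stranded fraction is recovered after
renaturation to a chosen Cot value (Cot = C0·t, the initial single-strand
nucleotide concentration times elapsed time, mol·s/L) and sequenced, the
resulting read set is depleted of each family in proportion to how far its
reassociation has progressed.

`cotfreq` implements the estimator built on this physics: map the reads of
two (or more) Cot-selected samples to a reference sequence carrying one
copy of the element of interest, record the fraction of all sequenced
reads that overlap that element in each sample, extrapolate those
fractions back to Cot = 0 — where no depletion has yet occurred — and
scale the Cot-zero fraction f0 to the whole genome:

    genome mass  = f0 · G            (bp)
    copy number  = ⌊ f0 · G / L ⌋    (element length L bp)

The floor is deliberate: every step of the chain loses element reads
(strict mapping thresholds, reads extending past element boundaries,
residual depletion not removed by the extrapolation), so the estimate is a
lower bound and is reported as "at least N copies".

## Reassociation model

Single-strand survival of a family with copy number n follows the classic
second-order hyperbola

    S(Cot) = 1 / (1 + k·Cot),    k = k_base · n,

with S = 1 at Cot 0 and strictly decreasing in both Cot and n.  The
per-copy rate constant `k_base` (L/(mol·s)) is a free parameter of the
simulator; real rates depend on temperature, salt and sequence complexity,
none of which are modelled.

**Default k_base = 1e-6.**  At the two study Cot values used throughout
(69.56 and 695.6 mol·s/L) this choice gives single-copy DNA survival of
0.99993 and 0.9993 (essentially untouched), a 500-copy moderately
repetitive family 0.966 and 0.742 (measurably but mildly depleted), and a
100,000-copy highly repetitive family 0.125 and 0.014 (largely removed).
That hierarchy — unique DNA retained, moderate repeats partially retained,
high repeats stripped — is what a Cot filtration aimed at the gene space
is designed to produce, and it keeps the two measured fractions inside the
regime where a two-point extrapolation to Cot zero is informative.

## Extrapolation to Cot zero

The default (`linear`) mode fits fraction = a + b·Cot by least squares
(exact interpolation for two points) and returns a.  The fit uses a
centred closed-form slope/intercept rather than a polynomial solver so
that exactly-affine input recovers the intercept to ~1e-15 even with Cot
values in the hundreds.  A `loglinear` mode fits fraction against
log10(Cot); such a model diverges at Cot = 0, so it is evaluated one
decade below the smallest measured Cot — a documented convention, chosen
because any other anchor is equally arbitrary.  Either way the result is
clamped to [0, 1] with a warning, since it is a proportion.

Linearity in Cot is itself an approximation: expanding S(Cot) for small
k·n·Cot shows the observed fraction is affine in Cot with intercept equal
to the true genomic fraction, but once a family is strongly reassociated
at the *lowest* measured Cot the relationship is far from linear and the
extrapolation collapses toward the depleted values.  The estimator is
therefore only as good as the choice of Cot values relative to the
element's copy number; see Limitations.

## Read mapping

The mapper re-implements the strict contract used for Cot-to-BAC
comparisons: by default a read is mapped only at 100% identity with at
least 90% of its bases aligned.  It is a deterministic seed-and-extend
design: non-overlapping k-mer seeds (default 16 bp) anchor candidate
diagonals on both strands, ungapped extension over the full read (clipped
only at reference ends) counts matches, and the best qualifying placement
wins, ties broken by lowest reference coordinate then + strand.  Two
definitions are fixed because upstream tools disagree:

* identity = matches / aligned read bases (clipped bases excluded);
* read coverage = aligned read bases / raw read length.

N bases never count as matches.  Seeds occurring more than `max_seed_hits`
times in the reference (default 5000) are masked, the standard guard
against low-complexity seed explosion; reads whose every seed is masked
go unmapped, which under strict identity only affects reads that are
themselves tandem-repetitive.  Gapped alignment is out of scope: the
simulator's divergence model is substitution-only by default, and at 100%
identity a gapped placement could never qualify anyway.

All tied-best placements are retained on each record.  The element-read
numerator counts a read if *any* tied placement overlaps the element by
at least 1 bp, so reads from a multi-copy family are not lost to
tie-breaking; each read counts once.  Element discovery by similarity
(`find_element_copies`) uses the same machinery at the thresholds
conventional for SINE annotation (identity > 84%, probe coverage > 69%)
with greedy best-score overlap suppression.

External alignments can be substituted through SAM ingestion (pysam):
identity is derived from the NM tag, falling back to MD; records with
neither are an error, and unmapped/secondary/supplementary records are
skipped and counted.

## Depth profiles

Windowed statistics (default window 100 bp) are computed in two forms
because the source formulas differ: a count track assigning each primary
alignment to the window containing its start, and a base-depth track,
per-window mean depth over global mean depth, in which uniform coverage is
1.0 everywhere.  The count track is normalised by both plausible
denominators (reads mapped to the reference; all sequenced reads) and both
columns are reported.  The final partial window is normalised by its
actual length.  Heatmap values are log2(norm_depth + 2^-10), the
pseudocount keeping empty windows at -10 raw and the display clip at
[0, 10] matching the conventional rendering range; raw values are always
retained alongside.  Reference coverage is the fraction of positions with
at least one aligned base.

## Synthetic genomes and Cot fractionation

The generator emulates the features of a repeat-structured genome that the
estimator actually touches: i.i.d. uniform background, interspersed
families planted at known copy numbers at uniform non-overlapping
positions (each copy independently substituted at the family divergence
rate; an indel mode exists but is off by default so the 100%-identity
contract stays clean), and optional rDNA-like tandem arrays
(18S–ITS1–5.8S–ITS2–28S plus intergenic spacer cassettes, tiled).  Truth
tables record copy number, element length and genomic fraction
(copies·L/G), and placements are exported as BED.

Cot selection is acceptance-rejection sampling: fragments get uniform
starts and truncated-normal lengths (default mean 250, sd 50, floor 50 bp,
emulating 454 reads), and are accepted with probability equal to the
survival of the family at the fragment midpoint (background = copy number
1).  The midpoint rule makes every fragment's class unambiguous, which is
adequate when reads are short relative to the spacing of elements.  A cap
of 1000·n_reads attempts guards against unreachable acceptance rates.
Read ids encode the true origin interval and family, so tests can score
composition without mapping.

What the simulator does **not** model: sequencing error (notably 454
homopolymer errors), paired ends, diploidy and heterozygosity, GC bias,
non-uniform fragmentation, real repeat sequence content, and partial
single/double-strand binding during hydroxyapatite chromatography.
Passing recovery tests therefore demonstrate the estimator's statistical
behaviour under clean kinetics, not robustness to platform artefacts.

## Known biases of the estimation chain

Two systematic effects make the copy-number estimate a lower bound, and
both are visible in the synthetic experiments:

1. **Kinetic depletion.**  The linear extrapolation removes depletion only
   to first order.  If the element is substantially reassociated already
   at the lowest Cot sampled, both measured fractions are small and the
   intercept lands near them, not near the true fraction.  With the
   default k_base = 1e-6 a 500-copy family extrapolates to ~99% of truth;
   at k_base = 1e-3 the same family is >97% depleted at Cot 69.56 and the
   extrapolation recovers only a few percent of truth — and no estimator
   could do better there, because the two fractions carry almost no
   information about copy number once depletion saturates.

2. **Read length versus element length.**  At 100% identity and 90% read
   coverage, a read can only be assigned to the element if it lies
   (nearly) fully inside a copy; with 250 bp reads and a 195 bp element
   almost no read qualifies, and even 50 bp reads cap the expected
   recovery at (195-50)/195 ≈ 74% of truth.  This is intrinsic to
   read-count frequency estimation with reads longer than the element,
   and it is the quantitative content of the "at least" phrasing attached
   to such estimates.

The end-to-end demo therefore reports the truth alongside the estimate,
and the acceptance experiment that runs the chain at strong-depletion
settings documents the collapse rather than hiding it.

## Pipeline, determinism, numerics

One YAML config drives `simulate → map → profile → estimate`.  A single
global seed is fanned out to per-stage child seeds by SHA-256 of
"seed:stage-label" (stable across machines, < 2^31), so stages can be
rerun independently; all outputs are byte-reproducible under a fixed seed,
with timings confined to the manifest.  The config hash in reports is
SHA-256 of the canonical JSON of the config minus the output directory.
Internally all coordinates are 0-based half-open; 1-based closed
coordinates appear only at I/O and report boundaries (element lengths
printed from annotations are closed-interval lengths).  Report floats are
written to 6 significant digits for stable golden comparisons.  Copy
numbers are floored, with an absolute 1e-6 snap guard so that an exactly
integral f0·G/L is not floored through float error.

Default problem sizes in the test suite (2 Mb genomes, 500-copy families,
20,000 reads per fraction, 3-copy tandem arrays up to 8 kb units) were
chosen as the smallest scales at which the statistical claims under test
are comfortably outside sampling noise.

## Limitations

* Tandem-repeat scanning reports perfect repeats only; diverged or
  interrupted tandem arrays are visible in the dot matrix but not called.
* The dot matrix is same-strand only by default (inverted repeats need the
  reverse-complement flag at the library level).
* The conserved-difference site counter treats N and all ambiguity codes
  as gaps and requires within-group fixation; it is a generic MSA column
  classifier, not a substitute for a phylogenetic test.
* Confidence in the copy-number estimate is conveyed by seed-replicate
  spread only; no sampling-error model is fitted.
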