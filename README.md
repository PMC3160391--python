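# cotfreq

Estimate the genome-wide frequency and copy number of a repeat element
from Cot-filtered sequencing data.

Large, unassembled genomes — ticks and other chelicerates are the
motivating case — are dominated by repetitive DNA whose abundance cannot
be counted from an assembly that does not exist.  Cot filtration gives an
indirect handle: denatured genomic DNA reassociates with second-order
kinetics, high-copy families faster than low-copy ones, so the
single-stranded fraction recovered at a chosen Cot value (Cot = C0·t,
mol·s/L) is depleted of each repeat family in proportion to its copy
number.  `cotfreq` maps reads from two or more Cot-selected samples to a
reference sequence (a sequenced BAC, say) under strict thresholds —
by default 100% identity and 90% read coverage — measures the fraction of
all sequenced reads overlapping an element of interest in each sample,
extrapolates those fractions back to Cot = 0, and converts the Cot-zero
fraction f0 into genome mass and copy number:

    genome_mass = f0 · G        copy_number = ⌊ f0 · G / L ⌋

for genome size G and element length L.  The floor reflects that the
chain systematically loses element reads, so the result reads "at least
N copies".

The package also provides the supporting computations used when
characterising repeat-dense clones: windowed read-depth heatmap tracks,
similarity-threshold element discovery (SINE annotation style: identity
> 84%, coverage > 69%), perfect tandem-repeat (SSR) scanning, self
dot-matrix and tandem-unit period estimation for rDNA-like arrays,
interval/exon-overlap arithmetic in both coordinate conventions, and
conserved-difference column counting in multiple alignments.  A
synthetic-genome simulator with known ground truth (interspersed repeat
families, rDNA-like tandem arrays, second-order Cot fractionation,
454-like reads) makes the whole chain testable without any downloads.

See `docs/methods.md` for the model, its assumptions and known biases.

## Worked example

The headline numbers for a 195 bp SINE (the tick Ruka element) whose
Cot-zero read fraction extrapolates to 0.42% of a 7.1 Gb genome:

```pycon
>>> from cotfreq import estimate_copies
>>> est = estimate_copies([(69.56, 0.0042), (695.6, 0.0042)],
...                       genome_size=7.1e9, element_length=195)
>>> est.f0, est.genome_mass, est.copy_number
(0.0042, 29820000.0, 152923)
```

0.42% of 7.1 Gb is 29.82 Mb of genome in this family — at least 152,923
copies of a 195 bp element.  The same numbers from the shell:

```console
$ cotfreq estimate --point 69.56 0.0042 --point 695.6 0.0042 --element-length 195
f0: 0.0042
genome mass (bp): 2.982e+07
copy number (at least): 152923
```

An end-to-end synthetic experiment (build a 2 Mb genome carrying a 195 bp
family at 500 copies, simulate Cot 69.56 and 695.6 read sets, map, count,
extrapolate) is one command:

```console
$ cotfreq run -o demo --seed 1
output directory: demo
f0 (Cot-zero fraction): 0.00126667
estimated copy number: 12
true copy number: 500
```

The large gap between estimate and truth is the method's documented
lower-bound behaviour at default 454-like read lengths: a 250 bp read can
only be assigned to a 195 bp element at 100% identity / 90% coverage if
it lies almost entirely inside a copy, so most element-derived reads are
unmappable (`docs/methods.md`, "Known biases").  The per-run report
(`demo/estimate.json`) carries the per-fraction counts, f0, the config
hash and the simulator truth for exactly this comparison.

Other subcommands: `simulate`, `map`, `profile`, `scan-ssr`, `dotplot`,
`msa-sites` (see `cotfreq --help`).

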