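# Methods

This note documents the models and procedures implemented in `lrqc`,
the defaults that matter, the numerical choices, what the synthetic
generator does and does not emulate, and the design decisions taken
where more than one reasonable reading existed.

## Estimated read accuracy

Per-base Phred scores `q_i` are converted to error probabilities
`p_i = 10^(-q_i/10)`; the read's error probability is the arithmetic
mean of the `p_i`, and the estimated accuracy is its complement. Only
Phred+33 encoding is accepted; other encodings are rejected rather than
guessed. The read-level Q score is recomputed from the mean error
probability (`-10·log10(mean p)`), not from the arithmetic mean of the
`q_i`: averaging on the probability scale is what the accuracy formula
does, and deriving Q from the same quantity keeps the accuracy, error
and Q columns mutually consistent (the mean of `q_i` would overstate
quality, by Jensen's inequality). Accuracy is a fraction internally and
rendered as a percent in the CLI/report.

Numerical note: for constant-quality reads the mean is taken as the
per-base value directly, so the closed form `1 - 10^(-q/10)` holds
bit-exactly; floating-point summation would otherwise be off by an ulp
for some read lengths. An empty read is an error, never accuracy 0.

GC content excludes ambiguous bases (N) from both numerator and
denominator; an all-N read reports a missing GC value, not 0. U (from
direct-RNA reads) counts as T.

## Observed accuracy

Reads are classified per aligned base into match / substitution /
insertion / deletion. Insertions and deletions come from CIGAR I/D
operations; the M operator is split into matches and substitutions
using, in order of preference, explicit =/X operators, the MD tag, or a
comparison against the supplied reference sequence. Soft and hard clips
are excluded from all counts — a clipped base is none of the four
classes — and `N` operations (spliced introns in RNA alignments) are
skipped entirely: an intron is not a deletion-type error. Only primary
alignments are scored (secondary and supplementary records are skipped
and counted), so each read contributes exactly one row.

`observed identification` (`N_mat / (N_mat + N_sub)`) is reported as
missing, not 0, for the degenerate case of an alignment with no
aligned M/=/X base. It is ≥ observed accuracy by construction, since it
ignores indels.

When the input is unaligned (FASTQ or unaligned SAM/BAM) plus a
reference, alignment is delegated to minimap2 with the platform preset
(`map-ont`, `map-pb`, or `-ax splice -uf -k14` for direct RNA), MD-tag
emission on and secondary alignments suppressed, followed by
`samtools sort`. The tool's own computation starts at the aligned
records; aligned BAM input bypasses the aligner entirely.

## Homopolymer identification

Reference homopolymers are maximal single-base runs of length ≥
`min_len` (default 4, configurable; runs of N are excluded). The
default is a compromise: runs of 2–3 are ubiquitous and essentially
always correct, so they dilute the signal, while platforms begin to
diverge at length ~4+.

Scoring rule (a deliberate, strict choice — "identification" is read
as exact reproduction): a run is correct for a read iff every run base
is aligned as a match (no substitution, no deletion) and no insertion
lies strictly inside the run, i.e. between two run bases. Indels at
the run boundary sit between the run and its flank and do not
penalize. An alignment must span the run plus one flanking base on
each side to be scored at all; otherwise the event is excluded and
counted as "unspanned" rather than silently dropped or scored 0.
Per-base-type accuracy over zero events is missing, never 0.

## GC bias

The reference is tiled into non-overlapping bins (default 1 kb,
`--binsize`). Trailing partial bins and all-N bins are excluded:
unequal bin lengths would make GC and depth incomparable across bins.
Depth is the mean per-base coverage from primary, non-duplicate,
non-QC-fail alignments (per-base coverage, not read starts, is the
standard reading of "sequencing depth"). Requiring coordinate-sorted
input, the depth pass indexes the BAM on the fly if needed.

Bins are bucketed by `round(100·GC)` into 101 integer categories. The
normalization scale is the narrowest contiguous category window
containing at least 90 % of the scored bins (`--coverage-threshold`);
among equally narrow windows the one whose center is nearest the modal
category wins, then the lower bound breaks remaining ties. The window
is found by exhaustive search over all ≤ 101·102/2 windows, which is
exact and cheap. Normalized depth is bin depth divided by the mean
depth of in-window bins, so the in-window mean is 1 by construction.
A user-supplied window (`--scale lo,hi`) replaces the automatic one;
the fraction of bins it covers is reported, and a window containing no
bins is an error, as is a zero mean depth inside the window (no
signal to normalize against).

## Regional methylation

bedMethyl input follows the modkit dialect: 9 tab-separated BED fields
with the modification code (`m` = 5mC, `h` = 5hmC) in column 4,
followed by 9 count/percent fields that modkit emits space-separated
within one trailing tab block (fully tab-separated 18-column files are
also accepted). Only chrom/start/end/code/percent are retained; the
percent-modified field is used (not N_mod/N_valid) and converted to a
[0,1] proportion. Because coverage is discarded at this point, region
summaries are *unweighted* means of site proportions — every site
counts equally. Sites are assigned to regions by half-open overlap of
the site start (`region.start ≤ site.start < region.end`); sites
matching no region are tallied as orphans, so assigned + orphans always
equals the input count. Regions with no sites report a missing mean,
never 0 — a region with no CpG calls is unknown, not unmethylated.
Fixed-width tiling keeps the trailing partial region (means are
length-insensitive, unlike depth).

## Synthetic data generator

The generator produces every input the tool consumes, with ground
truth, so all tests run offline:

* **References**: i.i.d. bases at a target GC (optionally redrawn per
  1 kb window from a clipped normal for GC-bias studies), with
  homopolymer runs planted at recorded positions and flanks forced to
  differ so each run is maximal exactly as specified.
* **Reads**: per reference base, deletion then substitution are drawn
  at the configured rates; a single-base insertion follows each kept
  base with the insertion rate. The emitted CIGAR/MD encode exactly
  the injected edits, and the truth table is written from the same
  draw — a generator self-test confirms that re-parsing the emitted
  alignment reproduces the truth, before those alignments are used to
  test the metric code. The truth SAM/BAM is written directly rather
  than via an aligner so that metric tests are isolated from aligner
  behavior. Base qualities are normal draws (default mean Q15, sd 3)
  rounded and clipped to [1, 60]; `analytic_mean_accuracy` gives the
  exact expected accuracy under that discrete model for calibration
  tests. All reads are forward-strand and of one configured reference
  span (default 1 kb).
* **Coverage**: `uniform` mode places exactly
  `round(depth · bias(gc))` bin-length reads on each bin — the
  generator's definition of bias-free (or exactly-biased) sequencing,
  with no shot noise; `poisson` mode draws read starts uniformly for
  realistic noise.
* **bedMethyl**: evenly spaced sites per region at a target proportion
  plus optional clipped Gaussian noise, written in the modkit dialect.

What this does *not* emulate: k-mer- or signal-conditional error
profiles, strand effects, chimeras, length distributions, mapping
ambiguity, or coverage waviness beyond the injected GC function.
Passing tests therefore demonstrate that the *metrics* are computed
correctly and recover known truth — not that real ONT/PacBio data will
show any particular value of those metrics.

Default study conditions used by the test suite: 1000 reads × 1 kb at
sub/ins/del = 0.05/0.02/0.02 (typical of raw ONT simplex data) for the
truth-recovery checks, and a 2 Mb genome (1 kb bins, per-bin GC ~
N(0.42, 0.05), uniform 10×) for the GC-bias checks. These sizes keep
the whole suite under a minute on one CPU while leaving sampling error
well below the asserted tolerances.

## Determinism

Every generator takes an explicit seed (numpy `default_rng`); the same
seed reproduces byte-identical FASTQ/BAM/bedMethyl outputs. The
analysis code itself is deterministic and serial; `--threads` is passed
only to minimap2/samtools, whose output does not depend on thread
count, so reruns produce byte-identical TSVs regardless of threading.

## Known limitations

* Observed error rates include true biological variants; on divergent
  samples the tool overestimates error, like all reference-based QC.
  Pre-masking variant regions in the BAM is the recommended mitigation.
* The homopolymer rule is strict (exact reproduction); tools using a
  length-tolerance would report higher identification accuracy.
* GC-bias normalization does not correct for mappability or copy
  number.
* bedMethyl handling trusts the percent-modified field; low-coverage
  sites carry the same weight as deep ones in regional means.
* The HTML report is rendered with stdlib string templating and
  embeds figures as base64 PNGs; styling is intentionally minimal.
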