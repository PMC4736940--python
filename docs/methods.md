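# Methods

This note documents the models and algorithms behind `msatgbs`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the simulation-based tests do and do not
demonstrate about real data.

## The construct and the demultiplexer

An amplicon is `fwdBarcode · fwdTail · fwdPrimer · insert ·
revPrimer' · revTail' · revBarcode'` (primes denote reverse complement).
Individuals are identified combinatorially by the (forward, reverse)
barcode pair; the sample sheet assigns pairs in row-major order with the
forward barcode varying slowest.

Demultiplexing mirrors the processing script such experiments use: each
read, and its reverse complement, is parsed 5'→3' by semi-global
(infix) Levenshtein matching of the four identifying elements inside
chained positional windows (element length + tolerance + 5 bp slack; the
reverse elements are sought from the 3' end on the reverse complement).
Defaults allow 2 errors per 10 bp barcode and 3 per primer, matching an
expected ~6% combined sequencing + PCR error rate (0.6 expected errors per
barcode).  All four elements must match uniquely and both primers must name
the same locus; ties, margin failures and double-orientation parses are
rejected with a reason code.

Two safety rules go beyond the plain tolerance test:

* **SAFE barcode sets.**  A set is safe when the minimum pairwise
  Levenshtein distance exceeds 2 × tolerance, so any read within tolerance
  of one code is strictly closer to it than to every other.  This is a
  sufficient condition for reads whose barcode carries at most `tolerance`
  errors.  The simulator generates its sets at pairwise distance ≥ 7
  (stronger than the ≥ 5 the rule needs) so that even a barcode carrying
  three or four errors — already rejected by tolerance — cannot fall within
  tolerance of a *different* code.
* **Identity margin.**  Semi-global matching scans a window that also
  contains tail bases and damaged-barcode remnants, so a wrong code can
  occasionally score well *in context* even when the codes themselves are
  far apart.  A barcode match therefore counts only if it beats the
  runner-up code by ≥ 2 errors (`BARCODE_MARGIN`).  This sacrifices some
  in-tolerance reads (assignment ~85–90% instead of ~93% on simulated data)
  and in exchange drives observed misassignment to zero in 10⁴-read
  simulations.  Rejection is always preferred over guessing: combinatorial
  identity is undefined for a read sitting between two codes.

## The error model the simulator emulates

Reads are full amplicons or their reverse complements (probability 0.5
each) with i.i.d. per-base errors at rate 0.06 — the combined sequencing +
PCR error rate reported for 454 amplicon data in the study system — split
40% substitutions, 30% insertions, 30% deletions (the platform is
indel-dominated; the split is configurable, as is an optional homopolymer
indel multiplier, off by default).  Coverage per genotype is negative
binomial (mean 30, dispersion 6) scaled by the 1:1:8 size-class pooling
weights.  Genotypes draw one or two alleles whose repeat counts lie in a
±5-copy band around a 15-copy reference, so allele lengths always differ by
whole motif units; a configurable fraction of genotypes are instead
*same-length* heterozygotes whose two haplotypes differ by a flank SNP
(80%) or a length-compensated indel (20%) — planted size homoplasy.  A
manifest records each read's true origin and the number of planted errors
falling in each identifying element, which is what makes exact scoring of
the demultiplexer possible.

What the simulator does **not** model: PCR stutter as a distinct slippage
process (the caller's stutter rule is still exercised by error-induced
one-unit artifacts), chimeric/recombinant amplicons, flowgram-specific
error structure, quality-score information (constant placeholder Q35), and
read truncation by default (a geometric 3'-truncation option exists but is
off so unit tests see complete constructs).  Passing tests therefore show
that the algorithms are correct under an indel-rich i.i.d. error process at
the reported rate — not that real 454 chemistry holds no further surprises.

## Why the allele caller realigns before it reads the histogram

At 6% per-base with a 60% indel share, a 300 bp amplicon carries on average
~5 insertions and ~5 deletions; the raw read length is truth plus a
Skellam-distributed net offset with standard deviation ≈ 3 bp.  Real
alleles at one locus differ by as little as one dinucleotide unit, so the
raw histogram's peaks overlap heavily and no peak rule can reach high
accuracy at moderate depth.  The manual procedure this package automates
always *verified histograms by read alignment*; the caller makes that step
explicit:

1. **Per-locus reference.**  All individuals share a locus's flanking
   sequence, so reads are pooled across individuals (capped at 240,
   stride-sampled) and a reference insert is built once per locus.  A
   medoid read seeds an iterated, protected consensus: substitutions follow
   column plurality, but insertions/deletions are edited in only above 50%
   support and never inside the repeat zone — within a repeat, unit-cost
   alignments park unrelated errors from different reads on the same
   canonical junction (indels are left-normalized, as in variant-file
   normalization), so column votes there can fake majority support.
2. **Window content.**  The reference's repeat window (zone located by
   exact tandem runs with interrupt merging, extended while the flank
   continues the period, ± 6 bp margin; boundaries slid outward until the
   14 bp flank anchors are repeat-free) is replaced by the read segment
   that best fits an idealized margins + pure-repeat model.  Candidate
   windows (best-fitting donors, donor zones grafted into consensus
   margins, and the raw consensus window) are validated on a read
   subsample by vote rate, then by median read-to-window distance —
   constant defects such as graft seams raise every read's distance and
   are selected away.
3. **Unit votes.**  Each read's tract window is extracted between unique
   flank anchors (fuzzy infix search guided by expected positions —
   placement-free, so a 40 bp tract extension cannot be silently absorbed
   as flank mismatches) and aligned against the reference window with *d*
   whole motif units edited in or out; the candidate span covers the locus
   size band.  The minimum edit distance wins.  Flank errors price every
   candidate equally and cancel.  A single indel in a short motif
   genuinely ties adjacent counts ("AC"-tract one base short is one
   deletion from *d* and one insertion from *d−1*): pairs abstain, and
   symmetric odd tie sets resolve to their middle member.
4. **Absolute calibration.**  Votes are relative to the reference, whose
   own content may be off the allele lattice.  The anchor is the modal
   whole-insert residual (read length minus reference length minus
   *d*·motif) over the largest vote cluster, aligned to a reference edited
   to that cluster's own length; indels private to a read (below 25%
   support within the cluster) are subtracted first, so only shared
   reference defects remain.  Off-lattice anchors trigger a content repair
   at the repeat cut and a re-vote (up to three rounds).

The corrected histogram — one bar per voted repeat count — then goes
through the classical peak logic with its named parameters: `min_depth` 5
(the five-read genotyping gate), `het_ratio` 0.3 (second peak accepted at
≥ 30% of the top peak), `stutter_ratio` 0.5 (a peak exactly one motif
below a larger peak is absorbed below half its height), `min_allele_reads`
2.  Peak ties break toward the locus size-band midpoint, then toward the
longer allele.  Raw amplicon and insert lengths are recorded alongside for
diagnostics.  Measured on simulated panels at the study conditions, ≥ 95%
of called genotypes at depth ≥ 10 match the simulation truth, with
heterozygote misses at depth 10–15 (minority allele undersampled below the
`het_ratio` bar) the dominant residual error.

## The homoplasy screen

Reads supporting one called allele length are a stack of possibly two
same-length haplotypes, so a real flank variant appears as an alignment
column where a consistent fraction of reads disagree.  The screen applies
the published rule — genotypes with ≥ 10 reads; a SNP or indel outside the
repeat structure counts as homoplasy at ≥ 20% of the reads — applied per
alignment column, plus error guards each argued from the error process:

* `min_variant_reads` 4: at marginal depth, 20% of the stack can be two
  reads, indistinguishable from coincident errors.
* Indel states on a base run of ≥ 2 need twice the fraction: left-
  normalization piles independent indel errors on the first column of a
  run (homopolymer errors being the platform's signature artifact).
* The outermost 2 columns (3 for indels) are excluded: insert boundaries
  come from fuzzy primer matches and wobble by a couple of bases.
* Alignment references are the per-locus reference edited to each allele's
  unit count, not the small read-group's own consensus, whose artifacts
  would masquerade as high-fraction variants; the reference's flank lengths
  also bound the repeat interval so a fragmented tract cannot expose repeat
  columns as flank.  Substitution states in the near-tract band are
  ignored only where the local context itself reads as repeat.
* A high-fraction (≥ 0.7) state recurring in > 60% of screened individuals
  at one locus (keyed from either insert end) is discarded: the reference
  derives from these same reads, so locus-fixed variation cannot be real —
  such recurrence marks a reference artifact, whereas genuine two-haplotype
  variants sit near 50%.

Planted variants at an exact 50% read fraction are recovered in ≥ 95% of
screened genotypes; variants at 10% stay below the 20% rule; with nothing
planted, ≤ 5% of screened genotypes yield any record.  The summary reports
the percentage of screened genotypes with ≥ 1 record, the number of loci
affected, and the SNP : indel split.

## Concordance statistics

A GBS genotype matches the reference (capillary) genotype when both
alleles agree after per-locus calibration — the modal integer offset of
(reference − GBS) over shared calls, because capillary sizes are
instrument-scale estimates rather than true base-pair lengths (mode chosen
over mean for robustness; calibration can be disabled).  Candidate models
partition the comparison records by read-depth bin (two-level [0,5)/[5,∞)
or three-level [0,5)/[5,10)/[10,∞), half-open to agree with the five-read
gate), motif-type label, and/or PCR size-class-combination.  The grouped
Bernoulli log-likelihood at the ML cell proportions is
`Σ k·ln(k/n) + (n−k)·ln(1−k/n)`; the combinatorial constant is omitted as
it is identical across models on the same records.  Read yield uses the
plug-in multinomial `Σ nᵢ·ln(nᵢ/N)` with K equal to the number of category
levels (empty cells contribute zero to the sum but count toward K).
Models are ranked by `AICc = −2logL + 2K + 2K(K+1)/(n−K−1)` with Akaike
weights `exp(−ΔAICc/2)` normalized over the compared set; n is the record
count of the analysed dataset.  Group contrasts use pooled-variance
two-proportion z-tests and Mann–Whitney U (exact for small tie-free
samples), both Bonferroni-corrected across the pairs tested.  The
correspondence curve reports the match percentage above each of the depth
thresholds 5, 10, 50, 100, 150, 200, 250, 300, 400, 500.

## Problem sizes and determinism

The shipped tests and the acceptance script run simulations sized for a
single CPU: panels of 16 individuals × 12 loci (≈ 6,000–11,000 reads),
three panels for recovery rates, five 48-genotype panels for the screen.
Every random draw flows from one integer seed through
`numpy.random.default_rng`; demultiplexing, calling and screening are
order-independent and deterministic, so repeated runs are byte-identical.
Known limitations: mononucleotide motifs give the vote lattice no spacing
and are not part of the simulated panels; interrupted repeat tracts are
modelled as pure tandem arrays when unit counts are edited; polyploid
calling, cross-run allele binning and null-allele inference are out of
scope.
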