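# Methods

This note documents the models, rules, numerical choices and limitations
behind `editquant`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and conventions

Amplicon sequences are uppercase ACGTN. Reference coordinates are 0-based,
half-open; the cut site is an inter-base coordinate. Protospacer positions
are numbered 1–20 in the 5′→3′ direction of the non-targeted strand (the
strand whose sequence equals the sgRNA spacer), the convention of the
base-editing literature; user-facing reports use these 1-based positions.
SpCas9 cuts bluntly 3 bp 5′ of the PAM, so the cut site is derived as the
bond between protospacer positions 17 and 18 — it is never user-supplied.
For amplicons whose protospacer lies on the − strand, bases are reported
after complementing into protospacer orientation; reads may be
reverse-complemented before alignment (orientation chosen by comparing
alignment scores of both orientations when `orientation="auto"`).

## Alignment

Reads are aligned to their amplicon only (amplicons are short PCR
products; no genome-wide mapping). The alignment is a fitting ("glocal")
alignment: the read is consumed end-to-end, unaligned reference overhangs
on both sides are free. Scoring defaults are match +1, mismatch −4, gap
open −6, gap extend −1 (a gap of length L costs 6 + L). These were chosen
so that one clean indel near the cut outscores a scatter of mismatches,
matching the one-indel-event-per-read model that cut-site indel counting
assumes; they are module constants, not claims about any external mapper's
scoring.

The dynamic program is the standard three-state affine-gap recursion
(match/mismatch, insertion, deletion states with full inter-state
transitions), filled under numba for speed; traceback prefers the diagonal
state and the leftmost end column. All equal-scoring indel placements are
then normalised by an explicit left-alignment pass (gap runs shift to
their minimal reference coordinate across matching context, insertions
rotating as they shift). Left alignment is idempotent and preserves the
read, which the property tests check by reconstruction. An exact
5′-anchored read (equal to the reference prefix) short-circuits to the
all-match alignment, which attains the score ceiling.

Optimality is checked against an independent oracle — an exhaustive
memoised recursion over (read consumed, reference consumed, previous op)
that scores alignments directly from op sequences — on randomized suites
(reads ≤ 30 bp, references ≤ 40 bp), and the oracle itself is validated by
true brute-force enumeration on tiny cases.

## Outcome classification

Reads failing the prefix-identity filter (< 15/20 exact matches over
reference positions [0, 20)) are `discarded`; mismatched,
deletion-covered and unaligned prefix positions all count as unmatched.
Passing reads are classified with mode-scoped precedence
tag > indel-class > substitution:

* `indel`: some insertion/deletion segment's left-aligned reference start
  lies in [cut − 2, cut + 2]. "Indels without mismatches" is read as: the
  indel event itself is a pure insertion/deletion operation; distal
  mismatches elsewhere in the read do not veto the call. The stricter
  reading (whole read mismatch-free) is available as
  `strict_indel_read=True`, and `span_counts=True` optionally counts
  deletions that start left of the window but span the cut. Neither flag
  is claimed to reproduce any external implementation; the defaults follow
  the printed rule strictly.
* `intended_sub`: every specified substitution present and no indel
  anywhere in the read.
* `intended_pe` / `background_indel`: the read's indel content (after
  left-alignment, with the intended edit itself canonicalised the same
  way) equals exactly the programmed edit / differs from it.
* `tag`: exact substring match of the dsODN 15-bp center fragment in
  either orientation. A tag read is by construction also indel-bearing; it
  reports as `tag` in tag mode and as `indel` in nuclease mode.
* A `combined` mode applies every enabled rule in the precedence order
  above, for samples that mix tag, prime-edit and substitution outcomes in
  one read set.

Frequencies are exact ratios of class counts. The denominator is the
number of reads passing the prefix filter (reads failing it leave both
numerator and denominator); `count_discarded=True` switches to the raw
total, since published descriptions do not pin this choice down. A sample
in which no read passes is reported with zero frequencies and a
`no_passing_reads` warning.

## Derived metrics

Editing profiles report, per protospacer position, the fraction of
non-indel passing reads whose target base (A for ABE, C for CBE) was
converted (A→G / C→T); using non-indel reads as the denominator is
consistent with the "without indels" substitution rule, and a flag admits
all reads instead. The editing window is positions 4–8 inclusive; all
other target-base positions are bystanders. Summaries are median and
interquartile range with linear-interpolation quantiles (the convention is
fixed here because graphing software conventions vary).

`off_on_ratio` and `normalize_activity` are per-pair ratios (off/on,
variant/reference), undefined (NaN with reason) when the denominator is
zero; normalisation is per target pair, not by aggregate medians — the
tests construct a cohort where the two differ. The on-target adenine for
off/on comparisons is the target-base position maximally edited by the
designated reference variant, ties broken to the smallest position (a
documented choice; real data rarely ties). Reporting filters: the
on-target activity must strictly exceed 0.70 ("exceeded" read as strict
inequality, unit-tested at the boundary), and records with editing < 0.05
are flagged low; every exclusion is logged with a rule id. GUIDE-seq
desk-scale metrics: candidate sites are retained at Hamming distance ≤ 7
from the 20-mer target, and specificity is 100·on-target reads / all site
reads. The full genome-wide GUIDE-seq pipeline (UMI consolidation,
background subtraction, genome mapping) is out of scope.

## Kinetics

Time courses follow `cleaved(t) = P·(1 − exp(−t/τ))`; the rate constant is
`k = 1/τ` (exact by construction in every fit). Fitting is bounded
nonlinear least squares (scipy TRF) with five starts: τ from the
half-plateau time plus log-spaced alternatives spanning the sampled range,
P initialised from the last observation, bounds P ∈ (0, 1.05], τ > 0. The
plateau is fitted rather than fixed at 1 because incomplete cleavage is
real for low-activity variants; `fix_plateau=True` reproduces the
constrained variant. All-zero courses return k = 0 with a `no_activity`
flag and `converged=False`. A fit whose τ̂ exceeds one third of the time
span is flagged `undersampled` (category mismatch): the sampling grid
categories fast (3–30 s), medium (3–300 s) and slow (3–3600 s) are chosen
as the narrowest category covering ≈ 3τ, with log-spaced 8-point grids.

The titration model is our formalisation of single (one-fold) turnover
with random enzyme–plasmid partitioning: each plasmid escapes cleavage
with Poisson probability, giving `intact(r) = exp(−a·r)` for nominal
protein:plasmid ratio r and active fraction a; active concentration is
a × nominal. The model family (one-phase exponential) is standard for this
assay; the mechanistic mapping from ratio to exponent is a design choice
documented here, and the raw fit parameters are always reported. Fits
require ≥ 4 ratios spanning both sides of 1:1; a statistically significant
*increase* of intact fraction with ratio raises a data-quality error
rather than returning a nonsense fit. The 1:3 plasmid:active-protein setup
check passes within ±10% of ratio 3.0.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
not a sequencer. Per read, one outcome class is drawn from a categorical
distribution (indel, intended prime edit, background indel, dsODN tag,
unedited remainder; their frequencies must sum to ≤ 1); intended
substitutions are then applied independently per position to unedited-slot
reads, so a configured substitution frequency is the marginal probability
of the intended-substitution class when no other class competes.
Sequencing error is i.i.d. per-base substitution applied after the class
mutation (no simulated sequencer indels), keeping truth classes
unambiguous. Reads are single-end from the amplicon 5′ end (so the prefix
filter applies directly), constant Phred 40, truncated to the read length;
read lengths below 25 bp are rejected because they cannot span the filter
prefix and the cut.

Two deliberate generator choices matter for exactness:

* Indels are drawn from a configurable profile (default: lengths ±1…±10
  uniform, start offsets −2…+2 around the cut) and **rejection-resampled
  until the left-aligned placement stays inside the configured offset
  range**; the truth table records the canonical placement. Without this,
  homopolymer context can slide a "cut ± 2" indel to cut − 3 after left
  alignment and truth would disagree with the window rule for reasons of
  pure coordinate convention.
* The dsODN is modelled as a blunt insertion of the canonical 34-bp
  GUIDE-seq duplex at the cut, either orientation with probability 0.5;
  only its center 15-mer matters downstream, and integration geometry
  beyond that is not modelled.

In prime-edit configurations, background indels are resampled if they
collide with the canonicalised intended edit, so truth classes stay
observationally distinct. Plain `indel` and `background_indel` are
intentionally *not* distinguishable to any classifier (both are "an indel
different from the intended edit"), so mixed-class test sets use one or
the other, never both.

All randomness flows from a single named seed through one
`numpy.random.Generator`; identical config + seed yields byte-identical
FASTQ and truth tables.

What passing tests on this generator do **not** show: robustness to PCR
amplification bias, paired-end overlap artefacts, realistic quality-score
distributions, sequencer indel errors, or chimeric reads — none of which
are modelled.

## Problem sizes and tolerances

The test suite and acceptance script use n = 2,000 reads per simulated
sample, ≥ 200 replicates for frequency-recovery coverage (3 classes × 4
frequencies), 500 randomized alignment-oracle cases, and 100 replicates
per τ ∈ {5, 50, 500} s (2% noise) and per active fraction ∈ {0.3, 0.6,
1.0} for kinetics recovery; the acceptance script runs a 60-replicate
version of the frequency sweep and 50-replicate kinetics sweeps as its
standing summary. Statistical assertions use 3-binomial-SE bands with
≥ 95% replicate coverage; noiseless fits are required to recover τ to
0.1% relative. Convergence tolerances are scipy `least_squares` defaults;
the best of the multi-starts is kept, so the reported SSE never exceeds
the SSE at the heuristic initialisation.

## Known limitations

* The aligner is O(read × reference) per read and intended for amplicons
  (hundreds of bp), not long references.
* Base-edit profiles assume one editor chemistry per sample (A→G or C→T).
* The editing-window definition is positional (4–8); sequence-context
  effects on deamination are not modelled.
* `normalize_activity` alternatives (aggregate-median normalisation) are
  noted but not implemented; the per-pair definition is the one used.
* Kinetics fits assume a single exponential phase; biphasic cleavage and
  enzyme–substrate binding kinetics are out of scope.
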