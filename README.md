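# editquant

Quantification of CRISPR editing outcomes from amplicon deep sequencing,
plus single-turnover in vitro cleavage kinetics — as a tested, reusable
pipeline exercised end-to-end on synthetic reads and simulated time courses
with known ground truth.

## What it does and for whom

Groups characterising engineered SpCas9 variants (increased-fidelity
nucleases, adenine/cytosine base editors, prime editors) typically quantify
editing by PCR-amplifying each target locus, deep-sequencing the amplicons,
and counting outcome classes per read. `editquant` implements that
quantification stack as a library + CLI:

* **Alignment** — each read is aligned semi-globally to its reference
  amplicon (read fully consumed, reference end-gaps free; affine gaps,
  match +1 / mismatch −4 / gap open −6 / extend −1; indels left-aligned).
* **Read filter** — a read is kept if it matches at least 75% of the first
  20 bp of the reference amplicon (≥ 15/20 exact matches).
* **Indel calling** — an indel is called when an insertion or deletion's
  left-aligned start lies within ±2 bp of the blunt cut site, which sits
  between protospacer positions 17 and 18 (3 bp 5′ of the PAM).
  `indel_freq = n_indel_reads / n_total_reads`.
* **Base editing** — a read carries the intended modification when every
  specified substitution (e.g. A5→G) is present *and* the read contains no
  indel. Per-position A→G / C→T profiles are partitioned into the editing
  window (protospacer positions 4–8, numbered 5′→3′ on the non-targeted
  strand) versus bystander positions.
* **Prime editing** — a read is an intended prime edit only when its indel
  content equals exactly the programmed edit; any other indel counts toward
  the indel background.
* **dsODN tag integration** — GUIDE-seq tag capture is detected by exact
  matching of the 15-bp dsODN center fragment `GTTGTCATATGTTAA` /
  `TTAACATATGACAAC` in either orientation. Desk-scale GUIDE-seq metrics
  (≤ 7-mismatch site retention; specificity = 100 · on-target reads / all
  reads) live in `editquant.metrics`.
* **Kinetics** — cleavage time courses are fitted with the one-phase
  exponential `cleaved(t) = P·(1 − e^(−t/τ))`, reporting `k = 1/τ`, with
  fast (3–30 s), medium (3–300 s) and slow (3–3600 s) sampling categories;
  active-enzyme titrations are fitted with the single-turnover
  Poisson-partitioning model `intact(r) = e^(−a·r)`.
* **Synthetic data** — `editquant.simulate` generates FASTQ read sets with
  a per-read truth table (configurable indel, base-edit, prime-edit,
  background-indel and tag frequencies plus i.i.d. per-base error) and
  noisy kinetics observations, so every stage is testable without any
  sequencing download.

## Worked example

The shipped demo simulates a nuclease-edited sample (500 reads, true indel
frequency 0.30, 0.1% per-base sequencing error) on a packaged 200-bp
amplicon and quantifies it:

```sh
editquant run --config src/editquant/data/demo.yaml --out demo_out
```

`demo_out/outcomes.tsv` then contains

```
sample_id      total_reads  n_indel  indel_freq
demo_nuclease  500          158      0.316
```

i.e. 158 of 500 passing reads carried an insertion or deletion starting
within ±2 bp of the cut site, an estimated indel frequency of 31.6% for a
configured truth of 30% (within two binomial standard errors at n = 500).
`demo_out/` also holds the simulated FASTQ, the per-read truth table and
calls, an allele-count table, and a manifest; rerunning the same config and
seed reproduces every file byte-for-byte.

The same pipeline pieces are available as a library:

```python
from editquant import ReadSimConfig, simulate_edited_reads, quantify_sample

cfg = ReadSimConfig(amplicon=ref, n_reads=2000, indel_freq=0.3, seed=1)
reads, truth = simulate_edited_reads(cfg)
table, calls = quantify_sample(reads, ref, mode="nuclease")
print(table.indel_freq)
```

## Scope notes

Reads are simulated single-end spanning the amplicon 5′ end; paired-end
merging, PCR bias, UMI structure and genome-wide off-target mapping are out
of scope (see `docs/methods.md` for the full model description and
limitations).
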