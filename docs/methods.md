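# Methods

This note documents the models, conventions and numerical choices behind
`paleorna`, and what the synthetic data can and cannot show about real
ancient-RNA libraries.

## Composition statistics

The five per-sample tallies (total post-trimming reads *T*; genome-,
mRNA-, rRNA- and tRNA-mapped reads *G*, *M*, *R*, *tR*) feed three
derived quantities, computed in exact integer arithmetic and rounded to
two decimals only for reporting:

- **Endogenous percent** = 100·G/T. Undefined (reported missing) at T = 0.
- **rRNA proportion** = 100·R/(G+M+R+tR). The denominator is a
  reconstruction: classes overlap (a read can map to both the genome and
  a transcript), and G+M+R+tR is the only denominator that reproduces
  every row of the published canid mapping summary exactly; we document
  it as such rather than as a first-principles definition.
- **RNA enrichment factor** = ((M+R+tR)/L_t)/(G/L_g), the per-base read
  frequency on transcribed references over that on the genome. Only the
  length *ratio* L_g/L_t enters; since the study's reference lengths are
  not published, `calibrate_length_ratio` solves the ratio from one row's
  printed factor (the implied ratio is ≈13.75 and agrees across all 12
  rows to <0.1 %, so any row serves as calibrator).

## Junction analysis

Exon–exon junctions are indexed at cumulative exon lengths within each
transcript (n_exons − 1 per transcript); splice junctions at both genome
boundaries of every intron (2 per intron). A read straddles junction J
iff `start ≤ J − h` and `end ≥ J + h` with overhang h (default 1 nt:
"crossing" is required, the minimal crossing depth is left configurable
and is reported in output). A read crossing several junctions counts once
per category, preventing double counting. The reported fold is the raw
EE/SJ ratio; per-junction normalisation (dividing each count by the number
of indexed junctions) is available as a flag. With SJ = 0 the fold is
reported as infinite alongside the counts.

## Damage model and profiling

Deamination is simulated in read orientation: a source C at distance i
from an end is read as T with single-end probability
`d(i) = d_max·exp(−λ·i) + b`, the two ends acting independently, so the
combined probability at position i of an L-long read is
`1 − (1 − d(i))·(1 − d(L−1−i))`. The flat component b models the elevated
interior C>U seen in ultrashort single-stranded libraries. No G>A damage
is introduced (single-stranded model); sequencing error is a separate
uniform substitution rate. Defaults for the "ancient" preset are
d_max = 0.3, λ = 0.5, b = 0.01 — chosen to give a clearly detectable but
not saturating terminal signal (≈31 % at position 0).

The profiler reports, per position from each end (default span 25), the
frequency of each of the 12 mismatch classes as mismatches over
reference-base opportunities, with opportunities recorded; positions with
zero opportunities are reported missing, never zero. For minus-strand
alignments both bases are complemented so the C>T column always reads in
read orientation. Parameter recovery holds to ±0.02 at 10⁵ reads when
alignments are placed from simulator truth; mapper-based profiles are
slightly damped because reads whose damage exceeds the mismatch allowance
(notably ultrashort reads, allowed zero mismatches) drop out — the same
seed/mismatch censoring that affects real ultrashort data.

## The internal mapper

A k-mer-seeded (k = 10), ungapped, best-mismatch mapper intended for
desk-scale references. The mismatch allowance follows read length: 0
below 20 nt, 1 for 20–31 nt, 2 from 32 nt. For allowance m, seeds are
taken at m + 1 disjoint offsets, so by pigeonhole any placement within
the allowance has at least one exact seed — the mapper provably finds the
optimum the brute-force scan finds (property-tested). Transcript mapping
searches the sense strand only (stranded small-RNA-ligation libraries);
genome mapping searches both strands. Multi-mapping ties are resolved by
a seeded uniform choice. Indels are not modelled: fragments are ≤80 nt
and transcript references are contiguous; this is a documented
limitation, not an approximation of any particular production aligner.

De-duplication collapses identical full-length read sequences, keeping
the first occurrence (single-end data; no coordinate-based dedup). It is
idempotent and retains the removed count for duplication-rate reporting.

## Method 2: coverage scoring

Mean coverage c_g = D_g/L_g uses total per-position depth, which for
ungapped alignments equals summed overlap lengths (the exact identity
Σ_g D_g = Σ_alignments (end − start) is asserted in tests). The 95th
percentile is computed with linear interpolation over all transcripts
including zero-coverage ones (the coverage table spans the whole
transcript set; a flag restricts to covered transcripts), and retention
is inclusive (≥). Gene-to-tissue pairing is argmax over the array row,
ties broken lexicographically by tissue label; all-zero rows are left
unpaired and logged, and gene-name matching is exact but
case-insensitive, with unmatched high-coverage transcripts logged and
excluded. Query–control comparison is OLS on the 10 per-tissue scores;
ranking is by r², ties broken by higher slope then label order; the top
call is flagged confident above a configurable r² floor (default 0.5).
Scores scale linearly under global coverage scaling, so P95 membership,
r² and the call are scale-invariant.

## Method 1: count-based comparison

- **TMM**: M and A values on genes positive in both columns, 30 %/5 %
  rank trims on M/A, inverse-asymptotic-variance weighted mean, factors
  rescaled to geometric mean 1. The reference column defaults to the
  sample whose upper quartile of scaled counts is closest to the mean
  upper quartile. The implementation matches edgeR's `calcNormFactors`
  to 1e-6 on test fixtures (cross-checked via Rscript).
- **Blind dispersion**: counts are scaled to a common library size and
  φ̂ is the median over expressed genes of max(0, (s² − x̄)/x̄²) — the NB
  variance relation solved per gene and robustly pooled, with no design
  matrix. The median makes the estimate robust but biased low at small
  sample counts (≈0.42 recovered for a true 0.5 at 12 samples); with few
  samples it should be read as an order-of-magnitude stabiliser input,
  not an inferential quantity.
- **VST**: for φ > 0 with k = 1/φ,
  `y = (2/ln 2)·asinh(√((x + 3/8)/(k − 3/4))) + log2(k)` applied to
  size-adjusted counts; y is strictly monotone, defined at 0, and
  satisfies y(2x) − y(x) → 1 for large x (log2-like scale). As φ → 0 the
  Poisson stabiliser 2√(x + 3/8)/ln 2 is used. The contract is these
  properties, not numeric equality with any particular R implementation.
- **Regressions**: the control's 95th-percentile genes (on the
  transformed scale, computed after the VST; a flag moves the filter
  before) index both variables; adjusted R² uses the n − 2 correction;
  p-values come from the slope t statistic; significance requires
  p < 0.05/m (Bonferroni; m = 5 comparisons gives α = 0.01, m = 3 gives
  0.0166) and a positive slope. Fewer than 3 shared genes flags the
  result unusable.
- **Ordination/clustering**: rows are centred by their global means and
  decomposed by SVD; the rank-2 reconstruction error equals the sum of
  squared discarded singular values (Eckart–Young, asserted). Sample
  distances are cosine, clustered with average linkage; leaf-order
  seriation is out of scope.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analyses rely on:
tissue-specific expression driven by a marker-structured 10-tissue array
(≈90 % of genes strictly marker-maximal), ultrashort fragment-length
mixtures (geometric decay on 15–30 nt plus a uniform 30–80 nt component),
two-end C>U damage, PCR duplication by resampling emitted reads (a
dup_target of 0.85 reproduces the 80.9–87.1 % duplicate range observed in
degraded libraries; modern presets use 0.30 against the reported
20.9–39.4 %), rRNA/tRNA/genomic-DNA composition fractions (ancient preset:
30 %/5 %/5 %, within the observed 5–40 % rRNA band), extraction blanks of
random sequence with a <0.1 % trace, and an in-silico fragmenter that
emits 35 subsets of lengths 15–49 nt from fresh subsamples (the stated
repetition count, 1 + 34; a 36-subset variant covering length 50 is one
flag away). Modern "≥200 nt insert" controls are emulated at 60–80 nt —
long enough to behave as unfragmented against 80–300 nt exons at toy
scale.

It does **not** emulate: realistic base-quality models or
platform-specific error spectra, indel damage, repeat structure or GC
heterogeneity of real genomes, alternative splicing, or aligner-specific
mapping biases. Consequently, passing tests demonstrate that the
*statistics* behave as designed under the assumed generative model — not
that any particular real library would yield the same numbers. Quantities
whose published values depend on the deposited reads (real-data r²
values, junction folds, GC offsets) are covered by property-level checks
on synthetic panels instead: tissue recovery across seeds, fragmenter
robustness (r² ≥ 0.85 against the unfragmented control, mirroring the
reported 0.88–0.99 range), damage-parameter recovery, and exact oracle
agreement for mapper, junction counter and depth accounting.

## Problem sizes and randomness

Test and demonstration runs use 40–300-gene references (genomes of
~50–400 kb), 10³–10⁵ reads per library, and 20-seed panels for the
end-to-end tissue-recovery property — sizes at which every stage's
behaviour is already asymptotic enough for the tolerances asserted, while
the whole suite runs in minutes on one core. All randomness flows from
`numpy.random.default_rng` seeded per stage; derived per-sample seeds are
simple affine functions of the run seed, recorded in run metadata, and
identical seeds reproduce byte-identical outputs (asserted for FASTQ and
report files).

## Known limitations

- The ungapped mapper cannot place reads spanning exon–exon junctions on
  the genome, so genome-space splice-junction counts see only contiguous
  (DNA-like) reads — which is exactly the contrast the junction analysis
  exploits, but means transcript-space and genome-space mappings are not
  interchangeable.
- rRNA proportion's denominator and the enrichment length ratio are
  reconstructions from published values (documented above).
- The dispersion estimator's small-sample bias (above).
- Tissue calls for a query whose true tissue is absent from the controls
  are reported as best-available with the confidence flag; the method has
  no abstention mechanism beyond the r² floor.
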