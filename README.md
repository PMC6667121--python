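# paleorna

Authentication and tissue-of-origin analysis for **ancient RNA (aRNA)**
sequencing libraries — the ultrashort (15–80 nt), chemically damaged,
heavily PCR-duplicated shotgun reads recovered from historical and
permafrost-preserved animal tissues.

When RNA survives postmortem for centuries to millennia, the resulting
libraries look nothing like modern RNA-seq: most fragments are shorter than
the usual 30 nt aDNA mapping floor, cytosine deamination introduces C>U
(read as C>T) substitutions, 80–90 % of reads are PCR duplicates, and the
endogenous fraction is dominated by rRNA. This package implements, as a
tested and reusable pipeline, the statistics used to establish that such a
library is authentic RNA rather than contaminating DNA, and to assign its
tissue of origin — together with a synthetic-data generator that emulates
these libraries so every stage can be exercised end-to-end without any
external download. It is aimed at palaeogenomics researchers evaluating
candidate aRNA datasets and at methodologists studying how ultrashort reads
behave in transcriptome analyses.

## What it computes

**Composition metrics.** From the five per-sample read tallies — total
post-trimming reads *T*, genome-mapped *G*, mRNA-, rRNA- and tRNA-mapped
*M*, *R*, *tR*:

- endogenous percentage `100·G/T`;
- rRNA proportion `100·R/(G+M+R+tR)`;
- RNA enrichment factor `((M+R+tR)/L_t) / (G/L_g)` — the per-base read
  frequency on transcribed references over the per-base frequency on the
  genome (lengths `L_g`, `L_t`); authentic RNA shows strong enrichment,
  DNA does not;
- duplication rate `1 − distinct/total` over full read sequences.

**Junction straddling.** Reads crossing an exon–exon junction (with a
configurable minimum overhang on both sides) can only derive from spliced
transcripts; reads crossing intron–exon (splice) boundaries indicate
precursor mRNA or DNA. The EE/SJ fold separates RNA from DNA libraries.

**Damage profiles.** Positional mismatch frequencies from each read end
(counts over reference-base opportunities), mapDamage-style. A
single-stranded RNA library shows C>T decaying from the ends with no
complementary G>A excess; an end-composition table around 5′ read starts
exposes the excess-purine fragmentation signature.

**Method 2 — coverage-based tissue scoring.** Per-transcript mean coverage
`c_g = D_g / L_g` (total depth over transcript length) is computed, genes
at or above the 95th percentile are kept, each gene is assigned its
most-associated tissue by argmax over a 10-tissue expression array, and
tissues accumulate scores `S_t = Σ c_g`. A query sample is compared to each
control by OLS on the 10 per-tissue scores and assigned the control tissue
with the highest *r*². Depth-based scoring deliberately removes the
fragment-length bias that read counting suffers when two 25-nt reads would
outweigh one 50-nt read.

**Method 1 — count-based comparison.** TMM normalisation, a blind
negative-binomial dispersion estimate, an Anscombe-type variance-stabilising
transformation to a log2-like scale, 95th-percentile gene filtering per
control, and pairwise regressions with Bonferroni-corrected significance
(α = 0.05/m, positive slope required), plus SVD ordination biplots and
cosine-distance hierarchical clustering.

**Simulator.** Toy genome with spliced gene models (mRNA/rRNA/tRNA), a
marker-structured 10-tissue expression array, and a read simulator with a
two-component fragment-length mixture, two-end exponential-decay + flat
C>T damage `d(i) = d_max·e^(−λi) + b`, PCR duplication, composition
fractions, sequencing error, extraction blanks, and an in-silico
fragmenter that turns long modern reads into 35 subsets of 15–49 nt. Every
simulated read carries ground truth for parameter-recovery tests.

## Worked example

```
paleorna simulate --seed 7 demo/fixtures
paleorna method2 --reference demo/fixtures/reference \
    --control skin=demo/fixtures/control_skin.fastq \
    --control liver=demo/fixtures/control_liver.fastq \
    --control muscle=demo/fixtures/control_muscle.fastq \
    --control cartilage=demo/fixtures/control_cartilage.fastq \
    --query ancient=demo/fixtures/ancient.fastq --outdir demo/m2
paleorna authenticate --reference demo/fixtures/reference \
    --sample ancient=demo/fixtures/ancient.fastq \
    --sample blank=demo/fixtures/blank.fastq --outdir demo/auth
```

`demo/m2/calls.tsv` — the degraded query (simulated skin: ultrashort
fragments, deamination, 85 % duplication) is correctly assigned to the skin
control with a strong regression:

```
sample_id  top_call  r2                 confident
ancient    skin      0.862725238344101  True
```

`demo/auth/composition.tsv` and `junctions.tsv` — the ancient sample shows
high endogenous content, rRNA-rich composition, ~85 % duplication, and
far more exon–exon than splice-junction straddlers, while the blank maps
at 0.1 % with zero junction hits:

```
sample_id  endogenous_percent  rrna_proportion  enrichment_factor  duplication_rate
ancient    69.8                17.72            1.90               0.8538
blank      0.1                 0.0              0.99               0.0

sample_id  exon_exon  splice  fold
ancient    41         7       5.86
blank      0          0       —
```

(The enrichment factor is modest here because the toy genome is mostly
transcribed; on a mammalian genome, where `L_g/L_t ≈ 14`, the same
composition yields ~15-fold enrichment.)

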