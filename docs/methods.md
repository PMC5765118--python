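# Methods

## The measurement model

### Intron retention

Internally every interval is 0-based half-open on genomic contigs; GTF
input/output converts from the format's 1-based inclusive coordinates and
SAM positions are converted on read. For each intron (the gap between two
consecutive exons of a transcript; introns with identical coordinates
across transcripts are merged, since retention is a genomic measurement)
and each sample the pipeline computes:

* **intronic abundance** — the median per-base depth of strand-compatible
  reads over the intron's *measurable region*: intron positions not
  overlapped by any exon of any transcript nor by an annotated feature of
  an excluded type (default `{miRNA, snoRNA}` — independently expressed
  small RNAs residing in introns would otherwise masquerade as retention).
  The median was chosen over the mean for robustness against residual
  edge effects and localized artifacts, and because it is directly
  testable against a brute-force per-base pileup oracle.
* **exon splice abundance** — the number of reads carrying an alignment
  gap (CIGAR `N`) whose interval equals the intron exactly. Both
  boundaries must match; partially overlapping gapped reads count for
  neither term (conservative junction evidence). Multi-gapped reads are
  evaluated per gap and counted at most once per intron.

The IR ratio is `intronic / (intronic + splice)`, in [0, 1], missing when
both terms are zero. Monotonicity in the intronic term and the analytic
cases (30/70 → 0.3, x/0 → 1, 0/0 → missing) are asserted in tests.

**Retention filter.** An intron counts as retained in a sample when its
IR ratio is non-missing and strictly greater than that sample's first
quartile of non-missing IR ratios (the quantile is a parameter,
`quantile_cut = 0.25` by default), and retained in a group when this holds
in at least 2 of 3 replicates (`min_replicates`). Differential testing is
restricted to introns retained in at least one of the two compared groups.

**Strandedness.** The library protocol is configurable:
`reverse` (dUTP-style, default: the read maps antisense to the fragment),
`forward`, or `unstranded`. Strand filtering applies to both depth and
junction counting.

### Junction windows and translation

For each retained intron, the spliced exon–exon junction window takes up
to 75 nt from the 3′ end of the mRNA-upstream exon and up to 75 nt from
the 5′ start of the mRNA-downstream exon. The window is deliberately
assembled from *spliced* exonic context: a genomic window centered on the
junction would contain intron sequence and could not encode
junction-spanning peptides. Exons shorter than the flank truncate the
window (no extension into the next exon — the simplest defensible
convention). Minus-strand windows are reverse-complemented so sequences
read 5′→3′ on the mRNA; the junction offset `L` (length of the upstream
flank) is carried through all downstream coordinates. Each window is
translated in frames 0–2 with the standard code, stops rendered `*`,
unresolvable codons `X`, trailing partial codons dropped.

### Peptide matching

Matching is exact substring search of peptides against the frame
translations (every occurrence reported), with optional I/L equivalence
(off by default: the isobaric ambiguity of spectral search need not be
inherited by sequence-level matching). Matches containing `*` are
discarded. A match with amino-acid span [a, b) in frame f has coding
nucleotides [f + 3a, f + 3b); it spans the junction iff
`f + 3a < L` and `f + 3b > L` — at least one coding base on each side.
Per junction, spanning-peptide abundances are summed per sample before
fold-change and significance are computed (the aggregation is a package
convention; no in-silico tryptic digestion is performed, so matching
operates on full frame translations).

## Differential statistics

With triplicates there are only C(6,3) = 20 distinct two-group label
assignments, so a per-feature permutation test cannot produce p < 0.05.
The default test therefore pools permuted statistics across all features
into one null distribution — valid under the null because features are
exchangeable on a common scale (log2 intensities for proteins, IR ratios
for introns, log2(1+x) for junction-peptide sums and FPKM). An exact
per-feature enumeration over the 20 assignments is provided as an audit
mode.

The statistic is a variance-stabilized two-sample t:

    t = (mean_t − mean_c) / (s0 + sp · sqrt(1/n_t + 1/n_c))

with `sp` the pooled standard deviation and `s0` a constant offset,
defaulting to the median pooled standard error across features (the
SAM/Perseus convention). The offset matters at this sample size: the
permutation null of the plain Student t on 3v3 data is exactly t with 4
degrees of freedom, whose heavy tails are dominated by features with
accidentally tiny variance — under a pooled null even a 10-standard-
deviation effect then cannot clear a Bonferroni-adjusted α of 0.01, and
the t's own χ²₄ denominator makes detection erratic. Bounding the
denominator below by s0 restores a light-tailed null and stable power,
while `s0 = 0` recovers the plain t. This is a constant offset, not
empirical-Bayes variance shrinkage.

Pooled permutations are sampled uniformly with the observed labeling and
its mirror excluded, so the null is built from genuinely mixed groups;
p-values use add-one smoothing, `p = (1 + #{|t*| ≥ |t|}) / (1 + N)` with N
the pooled null size (10 000 permutations × features by default), and are
deterministic given the seed.

**Calls.**

* *Proteins*: effect = difference of log2 median summaries of the three
  replicates; significant iff adjusted p ≤ α = 0.01 (Bonferroni by
  default) **and** linear fold-change ≥ 1.2 or ≤ 1/1.2.
* *Introns*: effect = mean(treated IR) − mean(control IR); significant iff
  BH-FDR ≤ 0.01 (Bonferroni available); "removed" = significant with
  negative effect.
* *Transcripts*: FPKM = count / (kb of union exon) / (millions of mapped
  fragments); expressed when the group-mean count ≥ 10; effect = log2
  ratio of group mean FPKM with the same permutation machinery, gated at
  |1.5| fold-change and FDR ≤ 0.05. This is a deliberately simple
  substitute for a negative-binomial count model, adequate at the scale
  the generator produces; it is not a replacement for DESeq2 on real data.

**Integration.** A gene×stimulus pair is `validated` when a significantly
removed intron (negative ΔIR) coincides with a significant *increase* of
its protein or of its junction-spanning peptide signal; `partial` when
only one side of the evidence is present; `not_significant` otherwise.
Junction-peptide significance uses the same permutation machinery at
FDR ≤ 0.01 (the convention for the peptide layer is a package choice; the
underlying study reported these changes without stating a test). Stimulus
partitions (COLL-only / TRAP-only / common, with sign concordance of
common responders) are asserted disjoint and exhaustive on every run.

## The synthetic-data generator

The generator emulates the study design the pipeline targets — 3 control + 3
replicates per stimulus (COLL, TRAP) — with known ground truth:

* **Genome/annotation**: independent single-transcript genes (2–4 exons of
  80–130 nt, introns of 90–160 nt, i.i.d. uniform ACGT) on one contig per
  gene; ~5% of introns receive an embedded snoRNA feature to exercise the
  exclusion mask.
* **Alignments**: per intron and sample, `depth_per_gene = 60` coverage
  units are split binomially by the true IR: K ~ Binomial(60, IR) units
  become uniform intronic pre-mRNA coverage (reads may straddle the
  intron/exon boundary, so the median depth estimates K without edge
  bias) and 60 − K become junction reads whose gap equals the intron
  exactly. Spliced exonic reads (Poisson, mean 60 per gene) are placed
  within single exons so they never alias a junction. Read orientation
  encodes the gene strand under the configured protocol.
* **Baseline IR**: Beta(2, 5) across introns (most introns lowly
  retained, as in real transcriptomes); removal targets are drawn with
  baseline Uniform(0.5, 0.85) — removal effects are only meaningful on
  retained introns — and shifted by ΔIR = −0.4 (clipped to [0.01, 0.99])
  in treated samples. Default removal counts (16 COLL, 12 TRAP, 5 shared
  among 120 genes) scale the study's proportions to desk size.
* **Proteins/peptides**: intensities are log-normal,
  2^(base + log2FC·1[group] + N(0, 0.1)), base ~ N(10, 1.5) in log2 —
  TMT-like numbers. A `junction_peptide_rate = 0.8` fraction of removal
  genes is flagged *spliced and translated*: they receive a +1 log2FC
  protein effect and emit one 10-mer junction-spanning peptide taken
  verbatim from the package's own frame translation (stop-free by
  construction; in the rare case no stop-free spanning window exists in
  any frame the gene emits no peptide). Additional ±1 log2FC proteins are
  planted on non-removal genes to populate the stimulus partition. mRNA
  levels are held constant across conditions, mirroring the biology of an
  anucleate cell in which protein changes are not transcriptionally
  driven.
* A count-level fast path (`simulate_ir_matrix`) draws IR ratios directly
  from the same binomial model without read placement; it is statistically
  equivalent to quantifying the generated alignments and is used for the
  large calibration sweeps.

All randomness flows from a single root seed via SeedSequence spawning;
fixed seeds give byte-identical output files.

**What the generator does not model** — and hence what passing tests do
not establish about real data: alignment and sequencing error, mappability
and GC biases, paired-end fragments, isoform structure and linked introns
(each intron's IR is independent), overdispersed count noise, peptide
detectability and missing values in MS, and shared peptides between
proteins. The generator validates the pipeline's logic and calibration,
not the upstream measurement technologies.

## Numerical conventions and degenerate inputs

* Quantiles use numpy's default linear interpolation; the retention
  comparison is strict (`>`).
* Features with zero variance in both groups and zero mean difference get
  t = 0 (p = 1); with s0 = 0 and a nonzero difference the statistic is
  ±inf, which the pooled null handles as an extreme value.
* Introns with a missing ratio in any involved sample are excluded from
  differential testing; junctions with no spanning peptide are reported
  as not detected rather than zero-change.
* Empty measurable regions yield intronic abundance 0 (ratio then driven
  by junction evidence alone).
* TSVs are written with `%.6g` floats, tab separation and `.` decimal;
  reruns with the same config and seed are byte-identical (checksummed in
  the run manifest).

## Problem sizes

Default test and acceptance runs use 10–300 genes (up to ~600 introns),
3v3 replicates at 60× per-intron coverage, 200-protein tables, and 10 000
permutations — sizes chosen so the full suite exercises every stage,
including brute-force oracle comparisons, on a single CPU in minutes. All
sizes are config parameters and scale up unchanged.

## Known limitations

* The operational definition of intronic abundance (median depth over the
  measurable region) is one of several defensible choices; tools differ
  in edge handling, and absolute IR values are not comparable across
  definitions.
* The pooled permutation null assumes features share a scale; grossly
  heteroscedastic features would make pooled p-values conservative for
  quiet features and liberal for noisy ones. The s0 offset mitigates but
  does not remove this.
* Transcript-level differential expression is a fold-change/permutation
  substitute, not a count model.
* Junction-peptide evidence is sequence-level; PSM-level FDR, missed
  cleavages and modifications are out of scope (tables are consumed as
  given).
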