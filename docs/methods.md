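# Methods

## Exact read containment as an alignment criterion

The quantification unit is read containment: read *r* counts for reference
*f* iff `seq(f)` occurs in *r* as a contiguous substring, with no mismatches
or indels.  This is sound for small RNAs because the mature sequence
(19–26 nt miRNA, 24–30 nt piRNA) is fully contained in a 75–150 nt read; it
is deliberately conservative relative to a mismatch-tolerant genome aligner,
whose detected feature set will be a superset.  Multiplicity within a read
is ignored (containment, not occurrence counting), and a read containing k
distinct references increments all k counters — no apportioning or unique
assignment.  Matching is forward-strand only by default, since small-RNA
library prep preserves insert orientation; reverse-complement search is an
explicit option (`rc_mode`).  `N` participates in no match.

The production matcher is an Aho–Corasick automaton (goto trie + failure
links, outputs merged along failure links).  The brute-force double loop
(`naive_count_oracle`) is retained as a second, code-independent
implementation; the test suite asserts exact equality between the two on
randomized instances (including N-bearing reads, overlapping patterns,
prefix-nested patterns, and duplicate sequences under distinct ids).
Distinct ids with identical sequences — multi-locus miRNA families — are
all kept and credited identically; collapsing them is left to downstream
interpretation.

## Preprocessing

* Adapter: 3'-end search for the leftmost position whose read suffix matches
  an adapter prefix with Hamming mismatches ≤ floor(0.1·L), overlap ≥ 3.
  The default adapter is the TruSeq small-RNA 3' adapter
  (`TGGAATTCTCGGGTGCCAAGG`); it is configurable because kits differ.
* Quality: 3'-end trimming by the standard partial-sum rule at cutoff Q20
  (scan from the 3' end accumulating `cutoff − q_i`; cut at the maximal
  positive running sum; ties broken toward the 3' end, i.e. minimal
  trimming).  An alternative whole-read rule (drop reads with mean Phred
  < 20) is available as `mean_quality_filter` for sensitivity analysis,
  since "quality < 20" is ambiguous between the two readings.
* Order: adapter removal, then quality trimming, iterated to a fixpoint.
  The iteration matters: truncation can expose a new terminal adapter
  fragment that a single pass would leave behind; each cut strictly shortens
  the read and quality trimming is idempotent, so termination is guaranteed
  and no surviving read ends in an adapter match under the overlap/error
  rules.
* Length: reads shorter than 15 nt after trimming are dropped.
  `reads_in == reads_out + dropped_short` holds on every run.
* Only R1 is quantified by default in paired-end data; the insert is shorter
  than either mate, so quantifying both mates would double-count.

Containment counting itself is insensitive to an intact 3' adapter, so both
raw and trimmed FASTQ are accepted by `quant`.

## SAM filter

"At least 18 aligned bases" is evaluated as the summed lengths of M, = and X
CIGAR operations, not as a literal `18M` token — a literal reading would
drop perfect 19M–30M alignments.  Unmapped (0x4), secondary (0x100) and
supplementary (0x800) records are excluded so each read counts at most once
per reference; secondary counting is available behind a flag because
upstream tools differ.  Coordinates are ignored: transcriptome references
are the features themselves.

## Differential expression

* **Size factors**: median-of-ratios over features with strictly positive
  counts in all samples.  Normalized columns are invariant to per-sample
  depth changes only up to one common constant (the geometric-mean shift);
  fold changes are fully invariant.  A pseudocount mode covers tables with
  no all-positive feature.
* **Effect size**: `log2((mean_case + 0.5)/(mean_control + 0.5))` on
  normalized counts.  Published DE packages each use their own shrinkage
  estimator; this transparent ratio-of-means is used consistently here.
* **Significance**: the three published packages (negative-binomial GLMs,
  moderated linear models) are *not* re-implemented.  Their result tables
  can be ingested for consensus calling; the built-in method is an exact
  two-group permutation test on the difference of group means of
  `log2(normalized + 0.5)`, labelled `method="permutation"`.  Exact mode
  enumerates all C(n, n_case) relabelings (252 for 5v5); p is the fraction
  of relabelings with |statistic| ≥ the observed |statistic| (ties counted,
  observed labeling included, so p ≥ 1/K; by mask/complement symmetry the
  5v5 two-sided floor is 2/252 ≈ 0.00794).  The observed statistic is taken
  from its own enumerated column so that identical floating-point rounding
  guarantees self-inclusion.  Sampled mode uses the (1 + exceed)/(1 + n)
  convention.
* **Adjustment**: Benjamini–Hochberg step-up, validated against a literal
  transcription of the definition.
* **Consensus rule**: a method supports a feature iff *that method's row*
  has adjusted p < alpha(method) and |log2FC| > 3 (strict inequalities,
  matching how thresholds are conventionally printed); a feature is a hit
  with ≥ 1 supporting method.  Default alphas: 0.05 on adjusted p (deseq2,
  limma, permutation) and 0.1 on FDR (edger).  Missing values never
  support.  The rule is monotone: relaxing any alpha or lowering the
  fold-change threshold never removes a hit.
* **Detection sets**: a feature is "detected" in a group when its count is
  nonzero in ≥ 3 of the group's 5 samples; per-group sets are partitioned
  into shared and group-unique features.

### The permutation floor and small-sample consensus calling

A consequence worth stating explicitly: with a 5v5 exact permutation test the
smallest attainable two-sided p is 2/252, so after BH over m features the
smallest attainable adjusted value when k features tie at the floor is
(2/252)·(m/k).  For m = 200 and k = 10 that is ≈ 0.159 — above any
conventional alpha.  A 5v5 permutation test therefore cannot, by itself,
deliver BH-adjusted calls at 0.05 over a 200-feature panel, however large
the effect; this is an information limit of the design, not an estimation
error (the injected features still separate perfectly in rank and effect
size).  In practice consensus calling at these sample sizes needs either
model-based tests with parametric tail resolution (the usual role of the
ingested external methods), fewer tested features, or more samples.  The
test suite asserts the attainable recovery properties (all injected
features exceed |log2FC| 3, occupy the p-floor, and no null feature is
called) and records the adjusted-p floor behaviour.

## qPCR ddCt

Per sample, `dCt = Ct(target) − Ct(housekeeping)`; `ddCt` is centred on the
*arithmetic mean* dCt of the reference group (the standard convention;
equivalently the geometric mean of fold changes), and fold = `2^−ddCt` with
amplification efficiency fixed at 2.  Technical replicates are averaged to
one Ct per sample first (configurable).  The reference group's mean ddCt is
0 and its geometric-mean fold is 1 by construction, and folds are invariant
to any common Ct shift.  The group comparison is an exact two-sided
Mann–Whitney U on per-sample dCt values (rank-equivalent to testing folds);
the exact null distribution of U is computed by the rank-sum counting
recursion, equivalent to enumerating all C(n+m, n) assignments.  With tied
values a mid-rank normal approximation is used and flagged.

## Simulator

The generator emulates two-group pooled small-RNA libraries with exact
ground truth:

* **Abundances**: baseline proportions default to a log-uniform draw over
  three decades (a generic skewed profile; real serum-exosome abundance
  distributions are not modelled), scaled to 1 − background fraction
  (default 0.1).  Case-group features are scaled by `2^lfc` for injected
  features, then each sample's expected proportions are renormalized so the
  library totals exactly `lib_size` reads — a fixed sequencing-depth
  constraint that slightly attenuates realized fold changes (visibly:
  injected log2FC 4 is typically estimated around 3.2–3.9).
* **Counts**: multinomial at dispersion 0; for dispersion φ > 0 the feature
  proportions are gamma-weighted (shape 1/φ) before the multinomial — a
  negative-binomial draw conditioned on the fixed total — so the
  conservation invariant (column sum + background = lib_size) holds exactly.
* **Reads**: reference + adapter + uniform-random filler, truncated/padded
  to a uniform-random length in 75–150 nt; qualities constant Q34.
  Background reads are rejection-sampled to contain no reference; feature
  reads are rejection-sampled to contain no *other* reference, and
  substitution errors (default rate 0) are re-validated the same way, so
  observed containment counts are ≤ truth always and == truth exactly when
  error-free.  Rejection sampling requires a nesting-free reference set
  (no sequence a substring of another); `random_reference_set` screens for
  this, and a nested set makes generation fail loudly at the retry cap.
* **Determinism**: every draw derives from the config seed via spawned seed
  sequences; identical configs produce byte-identical FASTQ files.

What passing simulator-based tests does *not* show: robustness to indels,
quality-dependent error profiles, 5' adapter contamination, ligation bias,
or realistic biotype abundance mixtures — the simulator's reads are
structurally ideal by design, which is exactly what makes the ground truth
exact.

## Problem sizes and numerical choices

The round-trip validation uses the generator defaults: 10 samples × 200
features × 50,000 reads, error-free; randomized matcher-equivalence
instances use 1,000 reads × 300 references; injected-effect recovery uses
five replicate simulations at 10 of 200 features with |log2FC| = 4.  Exact
permutation mode refuses designs beyond a configurable cap (default 200,000
relabelings) in favour of sampled mode.  Adapter matching tolerates
floor(0.1·L) mismatches; quality-trim ties cut minimally; BH uses a stable
mergesort so tied p-values keep input order; the permutation comparison uses
`≥` (conservative under ties).
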