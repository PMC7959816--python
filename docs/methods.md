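# Methods

## Scope and model

`svconfide` operates downstream of SV discovery: its inputs are a merged,
genotyped multi-sample SV VCF (DEL/DUP/INV; insertions and translocations
are out of scope because short-read paired-end/split-read callers of the
LUMPY family cannot resolve them reliably), per-sample read-depth tracks,
repeat annotation, the reference genome, long-read alignments for one
homozygous line, and sample metadata distinguishing outbred fish from
doubled-haploid (DH) lines. All internal coordinates are 0-based half-open;
VCF POS/END are converted on read (POS−1) and restored on write. SV size is
`end − start` in converted coordinates; when SVLEN is present and disagrees,
SVLEN wins with a logged warning.

## Thresholds

All thresholds live in `PipelineConfig` with these defaults (the values the
filtering recipe is known by):

| parameter | default | meaning |
|---|---|---|
| `min_sv_size` | 300 bp | step 1: minimum size (strict `<` removes) |
| `high_cov_threshold` | 200× | extreme-coverage mask (`≥` includes) |
| `region_merge_gap` | 1,000 bp | merge regions separated by strictly less |
| `min_lowcomplexity_len` | 200 bp | keep merged low-complexity intervals strictly longer |
| `dhffc_del_max` / `dhffc_dup_min` | 0.7 / 1.3 | carrier depth-consistency bounds |
| `dhffc_inv_low` / `dhffc_inv_high` | 0.7 / 1.3 | inversion neutrality band |
| `af_min` / `af_max` | 0.05 / 0.95 | step 5 frequency bounds (strict `<`/`>` remove) |
| `min_call_rate` | 0.8 | step 6 (strict `<` removes) |
| `slop` | 100 bp | breakpoint-match padding |
| `reciprocal_fraction` | 0.9 | mutual overlap alternative criterion |
| `min_support_reads` | 2 | reads needed to validate |
| `min_cigar_indel` | 50 bp | CIGAR indels count when strictly longer |
| `flank_size` | 1,000 bp | DHFFC flank width |
| `n_pcs` | 10 | PCs retained |
| `histogram_bin` | 20 bp | deletion size-histogram bin |
| `identity_full` / `identity_partial` | 0.95 / 0.80 | TE classification thresholds |

Boundary semantics follow the literal reading of the recipe: "less than
1,000 bp were merged" is strict `<`; "greater than 200 bp were then
retained" is strict `>`; "equal or above 200×" is `≥`. Half-open adjacency
(gap 0) always coalesces during normalization.

## DHFFC and the carrier-only decision

DHFFC (depth fold change relative to flanks) is the median per-base depth
inside the SV span divided by the median over the union of the two 1 kb
flanks (clipped at chromosome ends; undefined when the flank median is 0).
The published phrasing — conditions violated "in at least one sample" —
cannot apply to all samples: hom-ref samples sit at DHFFC ≈ 1 > 0.7, so a
literal all-samples reading would remove every deletion. Step 3 therefore
evaluates carriers (het or hom-alt) only, in two modes:

- **literal** (default): remove the SV when *any* carrier violates the
  type's condition;
- **support**: remove only when *no* carrier meets it.

Literal-retained ⊆ support-retained for any input. Undefined carrier DHFFC
counts as a violation in literal mode and as non-support in support mode
(conservative in both). Whether the high-coverage mask should be computed
per sample or pooled is equally ambiguous; the default takes the union of
per-sample ≥ 200× regions, with an across-sample-mean mode as alternative.
Step 5's AF is computed over all samples (DH lines included). Per-sample
DHFFC may be read from a `DHFFC` FORMAT field or recomputed from depth;
recomputation is the default and wins on conflict (disagreements beyond the
VCF's 6-significant-digit serialization are logged).

## Long-read validation

Breakpoint pairs come from two evidence classes: CIGAR `D` operations
strictly longer than 50 bp (deletions only), and split-read junctions.
Adjacent split segments, taken in read order on one chromosome, are typed by
geometry: same strand with a forward reference jump → DEL; same strand with
a backward jump → DUP (a tandem-duplication junction: the copy ends at the
duplication end and restarts at its start); strand flip → INV. The junction
is (reference end of the earlier segment, reference start of the later
segment), stored sorted. This mapping is an interpretation — the external
scripts the recipe refers to are not reproduced anywhere — and is stated
here as the package's definition. Insertion (`I`) evidence is extracted and
counted but never matched, since no insertion candidates exist.

A pair supports a same-type candidate when both breakpoint intervals,
padded by 100 bp slop, overlap the SV's breakpoints (taken as zero-width
points at `start` and `end` unless the VCF supplies confidence intervals),
or when the pair's outer span and the SV span overlap reciprocally by
≥ 90%. Matching is strand-insensitive. A read counts once toward the
≥ 2-read threshold even when it contributes both evidence classes; indel
and split support are tallied separately for reporting. Rates are rounded
half-up to one decimal.

## The synthetic generator

The generator defines the study conditions every test and the acceptance
script run under. Defaults: 3 chromosomes × 500 kb; a TE library with a
1,621 bp DNA-transposon analog (Tc1-mariner-like), an LTR-retrotransposon
analog with a 380 bp LTR (Gypsy-like; planted mostly as solo LTRs), and a
1,465 bp unclassified element; TE density 8% of the genome; 3 N-gaps;
100 DEL / 5 DUP / 2 INV truth variants (the ~95/5/<1% type proportions of
real high-confidence call sets), 40% of deletions removing exactly one full
planted TE copy (half of those the 1,621 bp family), the rest drawn from a
300 bp-shifted exponential with scale 1,172 bp so ~90% fall under 3 kb;
per-population allele frequencies from a Balding–Nichols model at
divergence F = 0.1 over 3 populations of 20 outbred samples plus 4 DH
lines; baseline coverage 30× (an even value so half-integer copy-number
multiples stay exact) with noise_sd = 0 by default; 3 long reads per
evidence class per SV with breakpoint jitter sd 20 bp clamped to
±(slop−1).

Depth is baseline × copy number / 2 (DEL het 1 copy, hom-alt 0; DUP het 3,
hom-alt 4; INV copy-neutral), so DHFFC closed forms (0, 0.5, 1.5, 2.0, 1.0)
hold exactly under zero noise; optional noise is added per 100 bp window
(truncated Gaussian) to keep the run-length encoding compact. One 2 kb
region is forced to 250× in every sample as the high-coverage planted mask.

Six decoys are appended, each violating exactly one cascade step: size
299 bp; inside the ≥ 200× region; copy-neutral depth under a DEL call
(DHFFC ≈ 1); a het forced into one DH line; allele count targeting
AF = 0.02; ⌈0.3·n⌉ missing genotypes. Unlabeled truth variants pass every
filter *by construction*: genotype vectors are redrawn until the realized
AF lies in [0.05, 0.95] with at least one carrier (DH lines are drawn
strictly homozygous), and implants keep 1.1 kb clear of the combined mask
and 2.2 kb from each other so DHFFC flanks stay at baseline. Two further
labels mark negative validation controls among the designated DH line's
hom-alt variants: two "uncovered" variants receive no reads and two
"single-read" variants exactly one; an adversarial flag shifts all
breakpoint evidence beyond both matching criteria.

What the generator does **not** emulate: sequencing error and read-length
distributions (alignments are synthesized directly, since validation
consumes alignments, not reads), mapping ambiguity in repeats, caller
breakpoint bias, linkage disequilibrium between SVs, and overlapping or
nested variants. Passing tests therefore demonstrate the correctness of the
filtering/validation logic under its stated model, not the error profile of
real call sets; real-data headline counts are out of scope.

## Numerical and design choices

- Interval algebra is exact integer arithmetic on sorted, disjoint,
  non-adjacent half-open intervals; every operation is tested against a
  per-base boolean-mask oracle on random ≤ 10 kb instances.
- Medians over run-length depth are weighted medians (average of the two
  middle bases for even counts), identical to the per-base median.
- TE identity uses end-gap-free global alignment (match +1, mismatch −1,
  gap open −2, extend −1) with identity = matches / alignment columns
  *including* terminal gap columns, so the score reflects coverage of the
  library sequence: a solo LTR scores ~LTR/full-length against the full
  element and 1.0 against the LTR, which is what separates full-element
  from solo-LTR calls. The original BLASTN settings are unstated; this
  scheme is the package's stated substitute.
- PCA standardizes dosages by √(2p(1−p)) (the convention of genetics
  tooling; a covariance mode is available), mean-imputes missing calls per
  SV, drops zero-variance sites, and fixes each PC's sign so its
  largest-magnitude loading is positive — coordinates are then invariant to
  sample and SV order.
- Histogram peaks: a bin is a peak when it strictly exceeds both neighbours
  and exceeds 3× the median bin count. Real spectra are sparse at the tail,
  so isolated singleton bins can technically satisfy the rule; the tallest
  peaks are what the profiler reports and what the TE classification step
  consumes.
- Chromosome spacing uses the full chromosome length (kb) over the SV count
  (undefined at zero SVs), not the spanned length.
- Table rounding is decimal half-up (not banker's), matching rates printed
  as 98.0/98.1/87.9.

## Problem sizes

Tests and the acceptance script run the default bundle above (≈ 1.5 Mb
genome, 113 candidate records × 64 samples, ~450 alignment records), a
500-SV × 60-sample PCA cohort over five seeds, and 200 random
interval-algebra instances — sizes chosen so the full suite exercises every
stage end-to-end in well under a minute of compute while leaving the
statistical checks (Hardy–Weinberg het fraction, PCA clustering) enough
power to fail loudly if the underlying logic regresses.

## Known limitations

- Multi-allelic records are rejected by the reader rather than split.
- Breakpoint confidence intervals (CIPOS/CIEND) are not parsed; SV
  breakpoints are points, which makes the slop criterion slightly stricter
  than a CI-aware matcher on real caller output.
- The split-read geometry-to-type mapping is a stated interpretation (see
  above); alternative conventions (e.g. typing by the later segment's end)
  would shift junction coordinates by one segment length.
- `high_cov_mode="mean"` recomputes segment means by scanning all tracks per
  breakpoint pair and is intended for cohort-scale tracks with few
  segments, not base-resolution bedgraphs of deep cohorts.
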