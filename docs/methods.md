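# Methods

This note documents the models, parameter choices and numerical rules
behind `g4access`, and what the synthetic benchmark does and does not
establish.

## pG4 scoring and calling

Per-base scores follow the run-length rule: every base in a maximal run
of *n* guanines scores +min(*n*, 4), every base in a cytosine run
−min(*n*, 4), and all other bases (including N and ambiguity codes,
which also break runs) score 0. Sliding-window means (window *W*,
step 1) are compared against a threshold *t*; windows with |mean| ≥ *t*
and the same sign are merged when they overlap or touch, each merged
span is extended outward to complete any same-sign base run crossing its
boundary, and the mean base score over the final interval is recomputed.

**Defaults.** *W* = 25 bp and *t* = 1.2, the customary operating point
for this scoring family; both are configurable. Soft-masked lowercase is
uppercased; coordinates are 0-based half-open everywhere, so BED output
needs no conversion.

**Region refinement.** The union of hit windows is typically wider than
the G-rich core that triggered it, and for an isolated short motif the
flanking sequence swept into the union dilutes the mean below *t*: a
21 bp telomeric repeat (best window mean 1.44 at *W* = 25) sits in a
~36 bp merged span with mean ≈ 1.0. Discarding such regions would make
the caller blind to exactly the motifs it is meant to find, so when the
full merged span fails the re-check the caller falls back to the densest
subregion: the best-scoring window, grown greedily one base at a time
toward whichever side yields the higher mean, while the mean stays at or
above *t*. Regions that pass the re-check as a whole are emitted
unchanged. All tie-breaks are mirror-symmetric — growth extends both
ends on an exact left/right tie (only when the doubly-extended mean
still clears *t*), and when the best window score is tied the leftmost
and rightmost tied windows are both grown — so that calling commutes
with reverse complementation: calls on the reverse complement are
exactly the mirrored, strand-flipped calls on the forward sequence.
A consequence of the fallback is that raising the threshold can split
one merged call into two denser ones; what is guaranteed (and tested)
is that no call ever appears at a locus without hit windows, and that
hit windows shrink monotonically with the threshold.

Emitted scores always satisfy |score| ≥ *t*; the strand is + for G-rich
(positive-mean) regions and − for C-rich ones.

## Feature annotation

Promoters are TSS windows, default 2000 bp upstream and 500 bp
downstream in gene orientation (minus-strand genes use the gene end as
TSS). Each unstranded peak receives exactly one class by priority
Promoter > Exon > Intron > Downstream (≤ 3000 bp past the 3′ end) >
Intergenic, with ≥ 1 shared bp under half-open arithmetic as the overlap
rule. Ties within a class resolve to the gene with the smallest
|TSS distance|, then lexicographic id. There are no UTR classes because
the simulator's two-exon gene models have none; the scheme is the
five-class one that can be constructed from the available inputs.

## Differential counts

The model is a two-condition negative binomial with a common per-region
dispersion, in the classic exact-test style:

- **Size factors** are median-of-ratios against the per-region geometric
  mean over samples (regions containing any zero excluded; fall back to
  total-count ratios when fewer than 50 usable regions), rescaled to
  geometric mean 1. The *effective library* of a sample is the
  geometric-mean total count times its factor: the factors already carry
  all relative depth, so depth is corrected exactly once. (Multiplying
  each sample's own total by its factor instead corrects depth twice and
  measurably inflates the exact test's false-positive rate whenever
  library sizes vary.)
- **log2 CPM** = log2((count + 0.5) / (effective library + 1) × 10⁶);
  the 0.5 prior bounds fold changes at zero counts.
- **Dispersion** is a per-region method-of-moments estimate
  max(0, (s² − m)/m²) on depth-normalised counts within each replicated
  condition (pooled by degrees of freedom), shrunk halfway toward the
  across-region mean of the raw estimates and floored at 10⁻⁶. With a
  single replicate per condition the dispersion is 0 with a warning.
- **Exact test.** Group pseudo-counts a, b are the group sums after
  scaling every sample to the common effective library. Conditional on
  T = a + b, each split (i, T − i) is scored by the NB probability of
  the two group sums (binomial when dispersion is 0); the two-sided
  p-value is the total conditional probability of splits no more likely
  than the observed one (probability-mass ordering, with a 10⁻¹⁰
  relative tolerance on the tie comparison). log2FC =
  log2((b + 0.5)/(a + 0.5)) corrected for unequal group sizes.
- **Multiplicity** is Benjamini–Hochberg step-up. Default calls: DAR at
  FDR < 0.1; DEG at FDR < 0.05 and |log2FC| > 2.

The moment estimator with 0.5 shrinkage is deliberately simple; its
known cost is an anti-conservative extreme tail when true dispersion is
moderate (≥ ~0.05) and replicates are few, since an underestimated
dispersion sharpens the conditional distribution. This matters only far
beyond the 0.1 FDR working point; it is why the demonstration
configuration below uses Poisson counts.

## Enrichment statistic

pG4 strand is collapsed for containment, and containment means ≥ 1 bp
overlap. The background rate p is the fraction of **all**
promoter-classified peaks containing ≥ 1 pG4 — DARs included, matching
the phrasing "of all the peaks detected in gene promoter regions". The
headline quantity is the upper binomial tail P(X ≥ k), X ~ Binom(n, p),
for the k of n promoter DARs containing a pG4, evaluated with the
regularised incomplete beta function (scipy) and cross-checked in tests
against exact rational arithmetic to 10⁻¹². Per-DAR count summaries
(mean/median/min/max) are computed over pG4-containing DARs, so the
range starts at ≥ 1; `count_mean_all`/`count_median_all` include
pG4-free DARs as zeros. With zero promoter DARs the report carries
n = 0, tail 1.0 and a `degenerate` flag. Tail probabilities are stored
at full precision; rounding to two significant figures happens only at
the presentation layer.

## Synthetic data generator

The generator emulates a two-condition accessibility study on a compact
genome: i.i.d. background sequence at GC 0.41 (human-like), one two-exon
gene per ~15 kb cell of each contig, peaks either centred on TSSs
(default 120 of 200) or placed in intergenic space beyond all promoter
and downstream windows, and 3+3 replicate libraries of NB counts with
log-normal depth variation (σ = 0.1) around a 10⁵-read mean. True DARs
multiply the treated-condition mean by 2^log2FC (default −2, i.e.
4-fold reduced). Defaults emulate the promoter-DAR structure the
enrichment stage analyses: 22 reduced promoter DARs, pG4 containment
0.955 among them and 0.809 across all promoter peaks.

Two design choices make the planted structure *exact* ground truth
rather than a noisy expectation:

1. **Deterministic containment targets.** The number of peaks receiving
   a motif is round(rate × n) — e.g. exactly 21 of 22 reduced promoter
   DARs and exactly 97 of 120 promoter peaks — with the choice of peaks
   randomised. Bernoulli planting would scatter the realised rates and
   make recovery tests assert on noise.
2. **Scrubbing of pG4-free peaks.** Random DNA at realistic GC contains
   incidental caller hits in a few percent of 400 bp peaks. Peaks
   designated pG4-free are therefore redrawn locally until the caller
   (at the scrub window/threshold, default 25/1.2) finds nothing
   overlapping them. Real genomes are not G4-sparse in this way: the
   synthetic background under-represents incidental G4 motifs by
   construction, which is exactly what makes containment flags exact.
   Scrubbing guarantees cleanliness only at thresholds ≥ the scrub
   threshold.

Motif planting replaces background bases in place (contig lengths and
all coordinates stay fixed), on a random strand (reverse complement when
minus), with 1–3 copies per designated peak. Truth files (motif BED,
DAR TSV) are written alongside the data. Identical configs (including
seed) produce byte-identical outputs; the three generator stages draw
from independent seeded streams so gene models do not change when only
count parameters move.

**What passing tests show.** Recovery of planted structure demonstrates
that the chain of computations is correct and internally consistent; it
does not demonstrate performance on real data, where G4 motifs cluster
in CpG-rich promoters, peak widths and depths vary, accessibility
changes are small, and fragment-level artefacts exist. The generator
makes no attempt to model read-level noise (no FASTQ/BAM).

### Demonstration configuration

`structure_demo_config` + `DEMO_DAR_FDR` (10⁻⁵) configure the end-to-end
demonstration in which the detected DAR set must coincide with the
planted 22: a 27 bp G₃(TTA G₃)₄ motif template (every 25 bp window inside
it scores ≥ 1.56, so planted copies are recovered regardless of
flanking sequence), |log2FC| = 4 and Poisson counts (planted regions
then test at p < 10⁻⁹), and the stringent DAR cutoff. The stringency is
principled, not cosmetic: BH at FDR q admits ≈ q·R·m₀/m expected false
discoveries whenever R true effects are recovered, so at the routine
q = 0.1 a run with 22 strong effects among 200 peaks carries ~2 expected
false DARs and the recovered set would rarely equal the planted one even
with a perfectly calibrated test. At q = 10⁻⁵ a spurious DAR is a
< 0.1% event. Routine analyses should keep the defaults (FDR < 0.1);
the demonstration threshold exists to make an exact structural identity
reproducible. The resulting report reads n = 22, k = 21, background
97/120 ≈ 0.8083 and binomial tail 0.0576 → 0.058 at two significant
figures.

## Numerical and degenerate-input rules

- All internal coordinates 0-based half-open; GTF converts at the
  reader/writer boundary only.
- Exact-test probabilities are computed in log space and normalised over
  the conditional support; p-values are capped at 1.
- Window means are exact (integer sums divided by the window), so
  threshold comparisons are reproducible across implementations.
- Contigs shorter than the window are skipped with a warning; peaks on
  contigs absent from the annotation are classed Intergenic with a
  warning; zero promoter DARs yield a degenerate report, not an error.
- Empty inputs that make a quantity undefined (feature distribution of
  zero peaks, background rate over zero promoter peaks, all-zero count
  matrices) raise errors naming the problem.

## Problem sizes

The test suite and the acceptance script use a 2 Mb single-contig genome
with 130 genes and 200 peaks for pipeline runs, a 5 Mb genome with 100
planted motifs for recovery, and 2000-region × 3+3 NB matrices over 10–20
seeds for differential calibration — sizes chosen so the full suite runs
in minutes on one core while keeping every statistical check
well-powered.

## Known limitations

- The caller reproduces the G4Hunter scoring rule but not any particular
  published implementation's region post-processing; region boundaries
  can differ from other tools at equal scores.
- The dispersion estimator is moment-based with fixed shrinkage; no
  trended or quasi-likelihood dispersion, no covariates, exactly two
  conditions.
- The binomial enrichment model treats promoter DARs as exchangeable
  draws from the promoter background; no permutation or rotation null is
  provided.
- The synthetic genome is i.i.d. with scrubbed peaks — no CpG islands,
  repeats, or clustered G4 density.
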