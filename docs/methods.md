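# Methods

## Scope and model

`hypobias` re-implements, as a tested pipeline over synthetic cohorts, the
analytical chain used to characterise a glioblastoma subset defined by a
bias towards DNA hypo-methylation: region-level differential methylation,
the hypo-bias statistic and its spectrum, composite astrocyte-signature
scoring with enrichment classification at bulk, single-cell and pseudo-bulk
level, immune-composition correlation, and a morphological invasiveness
index. Upstream processing (array normalisation, probe QC, read alignment,
clustering, batch correction) is assumed done and is out of scope; the
package starts from beta matrices, TPM/UMI matrices and binary masks.

## Differential methylation

Beta values β ∈ (0, 1) are the methylated signal fraction per CpG probe;
the M value is the log2-odds transform M = log2(β/(1−β)), clamped to
β ∈ [1e−6, 1−1e−6] so that boundary values stay finite. Cohort-level probe
summaries use the median over all tumour×comparator replicate pairings of
M differences.

The DMR caller is a deliberately simplified regional statistic. Full
DMR callers fit a moderated t per probe, smooth squared statistics and
control FDR; with two replicates per group the biological signal is
carried by the effect size and the region geometry, so this implementation
thresholds the Gaussian-kernel-smoothed mean Δβ directly:

1. per-probe Δβ = mean(tumour) − mean(comparator), listwise-dropping
   probes with missing values;
2. per chromosome, smoothed_i = Σ_j K((p_j−p_i)/σ)·Δβ_j / Σ_j K(·) with a
   Gaussian K, σ = λ/C, restricted to |p_j−p_i| ≤ λ;
3. candidates are probes with |smoothed Δβ| ≥ cutoff (ties included, a
   deterministic boundary);
4. consecutive candidates ≤ λ bp apart merge into a region; regions with
   ≥ min_probes candidates are emitted;
5. direction is the sign of the mean raw Δβ over the region's candidate
   probes; region span is [first candidate position, last + 1) in 0-based
   half-open coordinates.

Defaults: min_probes = 6, cutoff = 0.3, λ = 1000 bp, C = 2. The
recovery guarantees (tests) are stated for this statistic, not for any
external caller's output. Whether probe-level hypo/hyper tallies should
count all probes by raw sign or only candidates is a presentation choice;
`probe_direction_summary` reports both.

## Bias statistic and spectrum

Per comparison, hypo fraction = (# hypo DMRs)/(# DMRs); a comparison with
zero DMRs yields an explicit missing value, never 0. Rules:

- syngeneic: bias iff fraction > 0.60 (strict);
- all-comparators: bias iff every comparator's fraction > 0.50 (strict);
  the comparator count is taken from the input;
- spectrum bins on the mean fraction: [0, 0.5) none, then very_low, low,
  medium, high, very_high in 0.1 steps, boundary values in the upper bin.

Missing comparators are ignored in means; a line with a majority of
missing comparators is non-classifiable. Threshold comparisons use an
absolute tolerance of 1e−9 so that means of exactly representable
fractions (e.g. mean(0.7, 0.7, 0.7) = 0.699…98 in binary floating point)
do not straddle a bin edge; this changes no classification at the
resolution the fractions can actually take. "Patient-specific" DMR sets
are obtained by removing any region that overlaps (≥ 1 bp, half-open
intervals) a region called in any other patient — the declared
interpretation of per-patient privacy.

## Signature scoring

**ssGSEA.** For one sample, genes are ranked by expression (average ranks
on ties). Walking the list from the highest-expressed gene down, in-set
genes advance a weighted ECDF (weight = rank^α, normalised by the total
in-set weight) and out-of-set genes advance a uniform ECDF by 1/(N−m); the
score is the sum of the running difference over all N positions (an area
statistic). α = 0.25 by default. With normalisation on, the whole score
table is divided by its range (max−min), which is the scale on which the
cohort-mean enrichment thresholds are interpreted. Scores depend only on
within-sample ranks, hence are invariant under strictly increasing
per-sample transforms (a tested property).

**ACS.** The astrocyte composite signature is the deduplicated union of
component astrocyte gene sets. The packaged component lists are synthetic
stand-ins assembled from canonical astrocyte/OPC marker symbols (files are
suffixed `.synthetic.gmt` and say so); the builder, not the list, is the
deliverable — swap in curated GMTs for real analyses.

**Enrichment call.** A sample is ACS-enriched iff its ACS score exceeds
the cohort mean ACS score (mean over all scored samples) and is ≥ 10%
greater than every OPC score. The 10% margin is multiplicative
(acs ≥ 1.1·opc) and presumes non-negative normalised scores; when negative
scores appear, a warning is raised and the margin falls back to an
additive 0.1·|opc|.

**Module scores.** Per cell: mean log-normalised expression of the
signature genes minus the mean of a control set. Genes are binned into 24
equal-frequency bins of cohort-average expression and 100 control genes
are sampled (seeded) per signature gene from its bin. Control genes are
drawn from outside the signature — a deviation from the common
convention of sampling the whole bin — so that a uniform shift of the
signature genes moves the score by exactly that shift; with signatures a
tiny fraction of the transcriptome the numerical difference is negligible.
Cells are assigned the arg-max signature; exact ties fall to a declared
priority order and are flagged.

**Pseudo-bulk.** Raw UMI counts are summed per gene over each patient's
(filtered) cells before normalisation, then CPM and log2(x+1); the
pseudocount of 1 is the declared choice absent a stated prior count. The
ACS/OPC ratio divides the ACS score by the mean of the two OPC scores; a
zero OPC mean yields an explicit NaN.

## Statistics

Spearman's rho is computed on average ranks. For n ≤ 9 the p-value is
exact, enumerating all n! permutations of one margin (two-sided by
default); beyond that the t approximation is used. Gene-list overlap
significance is the hypergeometric upper tail P(X ≥ k) computed for an
explicitly supplied universe size N — there is no defensible silent
default for N, so it is a required argument. A two-sided variant delegates
to Fisher's exact test.

## Invasiveness index

Erosion and dilation are implemented by thresholding the Euclidean
distance transform, i.e. morphology with a discrete Euclidean disk: radii
are physical (μm), resolution-independent up to discretisation, and
opening is exactly idempotent. Pipeline per section: erode the tissue mask
by 35 μm and discard staining outside it; tumour core = 10 μm opening of
the staining with components < 10,000 μm² discarded; gross tumour =
dilate 75 μm → erode 100 μm → dilate 25 μm with components that do not
intersect a core discarded ("contains a core" = non-empty pixel
intersection); II = gross area / core area, NaN when there is no core.
Components touching the image border are kept and counted separately.
Specimen-level II aggregates sections by mean (median by flag). Masks are
binary inputs by design: the trained pixel classifier used to produce such
masks is not part of the method; a thresholding convenience with an
explicit user threshold is provided instead.

Discretisation accuracy: on disk phantoms at 1 μm/px the measured II is
within 2% of the analytic value, and within 3% across 0.5/1/2 μm/px. The
intermediate 75 μm dilation needs ≥ 75 μm of image margin beyond the
staining, otherwise border clipping biases the areas — the phantom
generator reserves 120 μm.

## Synthetic data: what it emulates, and what not

- **Methylomes**: baseline betas from a Beta(2,10)/Beta(10,2) mixture (the
  typical array bimodality), per-sample Gaussian noise (sd 0.05 default),
  planted 8-probe clusters spaced ≤ 200 bp (so λ keeps a cluster in one
  region) shifted by ±0.4 beta; background probes sit > λ apart. Not
  emulated: probe-type chemistry, batch effects, spatially correlated
  noise, copy-number interference.
- **Expression**: lognormal baselines with lognormal sample noise,
  signature genes multiplied by 2^log2fc (default 2) in enriched samples,
  TPM-normalised columns. Not emulated: gene length effects, count noise.
- **Cells**: gamma-Poisson (negative binomial, dispersion 0.5) UMIs;
  AC-like/OPC-like/immune types up-shift their marker panels 4-fold. Not
  emulated: doublets, ambient RNA, depth gradients.
- **Masks**: analytic disks (solid core, speck ring or scattered halo)
  with exact truth areas.

Passing recovery tests therefore demonstrates correctness of the
implementation under its stated model, not performance on real cohorts
with correlated noise and annotation error.

## Problem sizes

The recovery evaluations run 20-seed batches with 40 planted regions per
cohort (2000 probes, 2 replicates per group) for DMR recovery, 12 lines ×
3 comparators (1000 probes) for bias recovery, 8-sample expression cohorts
for enrichment, 3 seeds × 600 cells for assignment, and three phantom
resolutions — sizes at which the planted effects are comfortably above
the callers' thresholds while a full run stays in the tens of seconds.

## Known limitations

- The DMR caller does not estimate uncertainty; it is an effect-size
  caller and inherits the cutoff's sensitivity to between-replicate noise
  at small n.
- ssGSEA normalisation couples scores across the table (division by the
  global range): adding samples changes normalised scores, which is
  inherent to the formulation the thresholds are stated on.
- The all-comparators rule is sensitive to a single noisy comparator by
  construction (it is an AND over comparators).
- Interval overlap for patient-specific DMRs is quadratic per chromosome;
  fine at array scale, not tuned for millions of regions.
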