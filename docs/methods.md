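# Methods

## The measurement model

The assay profiles DNA methylation by coupling droplet-based single-cell
targeted PCR to digestion with a methylation-sensitive restriction
endonuclease (HhaI, recognition site `GCGC`). Genomic DNA in each barcoded
droplet is digested before amplification; an amplicon spanning a recognition
site can only amplify if the site was protected by methylation. Presence of
at least one read for an amplicon in a cell is therefore a binary
methylation call for the targeted CpG. Two error processes dominate:

- **False negatives (dropout).** A methylated (or undigested) site can still
  yield no read, through capture or amplification failure. The per-amplicon
  false-negative rate `p_i` is measured directly in an *undigested* control
  run of the same panel — without the enzyme, every absence is technical.
- **False positives (digestion failure).** An unmethylated site escapes
  digestion with a small probability and amplifies anyway. This is measured
  on *constitutively unmethylated* control amplicons in the digested sample,
  and sits well below 1% in the regime the toolkit targets, which is what
  justifies the one-read binarization cutoff.

Three further amplicon classes serve as controls: amplicons with no `GCGC`
site (non-HhaI) amplify regardless of digestion and carry the cell-calling
signal; constitutively methylated amplicons provide a digestion-insensitive
reference for cross-sample QC; and loci with imprinting-like intermediate
methylation can be included as biological controls.

## Panel design

Recognition-site scanning reports every (possibly overlapping) motif match
and, by default, removes matches overlapped by an occurrence of a two-CpG
context (`CGCGC`, `GCGCG` for HhaI): digestion of such a site would confound
two CpGs. `N` never matches and windows containing `N` are discarded.
Candidate amplicon windows (default 300 bp) are centred on the recognition
site — the placement within the window is not otherwise constrained, so
centring is the symmetric choice and overlapping windows are allowed but
flagged — and filtered to 45–65% GC, the range where amplification is
reliable; amplicons above 0.65 GC show elevated dropout and the error-model
diagnostic flags them.

CpG selection from bulk methylomes proceeds in three steps:

1. **Simulation.** Single-cell binary calls are simulated from group-mean
   bulk beta values: each simulated cell carries two alleles per CpG,
   methylated with probability β; a methylated allele yields signal with
   probability 1 − 0.2 (allelic FNR), an unmethylated one with 0.1 (allelic
   FPR); the cell-level call is the OR over alleles. The two-allele OR rule
   is a design choice (the error rates are stated per allele but no
   combination rule follows from them); a one-allele mode is available.
2. **Regularized classification.** An elastic-net-penalized multinomial
   logistic regression is fitted at the fixed penalty λ = e⁻⁴ with mixing
   α = 0.9 (glmnet parameterisation, mapped to scikit-learn's
   `C = 1/(n·λ)`; saga solver, tolerance 1e-7, no cross-validation); CpGs
   with any coefficient of magnitude > 1e-8 are selected.
3. **Augmentation and controls.** Pairwise differentially methylated CpGs
   (two-sided Welch t-test per group pair, Benjamini–Hochberg within the
   pair, FDR < 0.05 and |Δmean| ≥ 0.25) are added, deduplicated against the
   classifier's set. Constitutive controls require the threshold in *every*
   sample (max β < 0.06 / min β > 0.94) and are ranked by mean beta — the
   tie-break among qualifying CpGs is not otherwise determined, and the mean
   is the natural summary; the lists are truncated to 50 unmethylated and 30
   methylated. Intermediate-methylation (imprinting-like) controls use a
   configurable band, default 0.35–0.65 in all samples, as no numeric rule
   is standard.

The recommended sequencing depth is exactly multiplicative:
cells × amplicons × per-amplicon coverage (60–80×), e.g.
10,000 × 500 × 70 = 350 M paired reads.

## Synthetic data generator

The simulator emulates the paired digested/undigested experiment at the
level the downstream analysis consumes (counts per barcode and amplicon),
with defaults at the study conditions the toolkit targets:

- methylation state `M ~ Bernoulli(profile[i, type])` per cell and amplicon
  (or two alleles with an OR rule in allelic mode);
- undigested capture `~ Bernoulli(1 − d_i)`; digested capture
  `~ Bernoulli((1 − d_i)·(M + (1 − M)·fpr))` with digestion failure
  `fpr = 0.002`; non-HhaI amplicons ignore digestion entirely;
- reads given capture are shifted Poisson, `1 + Poisson(λ_i − 1)` with
  λ = 40 by default, so presence and "≥ 1 read" coincide — chosen because
  the binarization rule is defined on at least one read and the true
  read-count distribution varies between libraries;
- empty droplets draw `Poisson(0.2)` background per amplicon; doublet
  barcodes are element-wise maxima of two random cells' count vectors (a
  conservative union of detections), appended at the configured rate;
- dropout defaults in the tests and acceptance runs are drawn once from
  Uniform(0.05, 0.25), bracketing the FNR range observed in practice.

All randomness flows from a single seed through deterministically spawned
substreams, so every matrix is bit-reproducible. What the generator does
*not* emulate: read-level artefacts (chimeras, index hopping), depth
dependence of the FNR, GC-driven dropout structure, or correlated
methylation between neighbouring CpGs. Passing tests therefore demonstrate
correctness of the estimators under the stated error model, not robustness
to those real-data effects.

## Cell calling

Only non-HhaI control amplicons are used, since their counts are independent
of methylation. The read threshold is `min(10, 0.2 × avg)`, where `avg` is
the mean per-amplicon read count of the control amplicons over barcodes
whose *whole-panel* total reaches 8 × the number of panel amplicons (the
coverage floor uses the full panel; the averaging uses the controls — the
vendor-derived rule leaves the averaging population ambiguous, and this
interpretation is unit-tested as the contract). A barcode is a cell when it
has strictly more than the threshold in at least 70% of the control
amplicons (strict at the threshold, inclusive at the fraction). Doublet
flagging is left to external tools; the output table carries a placeholder
column.

## Error rates and filtering

FNR per amplicon is the fraction of called cells with zero reads in the
undigested control (the MLE of a Bernoulli dropout); FPR is the fraction of
called cells with ≥ 1 read on constitutively unmethylated amplicons in the
digested sample, summarised by the lower median (deterministic for even
counts). Rates are computed after cell calling only. High-performance
amplicons are those with FNR strictly below 0.25. Cross-sample QC correlates
per-amplicon detection fractions on digestion-insensitive controls (non-HhaI
and constitutively methylated) between samples.

## Binarization, distance and clustering

Calls are 1 iff an amplicon has ≥ 1 read. Cells (or CpGs) are compared with
the asymmetric binary distance d = (n10 + n01)/(n11 + n10 + n01) — joint
absences carry no information in this assay; pairs with an empty union get
distance 0 (reference implementations differ here, so the convention is
fixed and documented). Clustering is Ward's minimum-variance method with
ward.D2 semantics (Lance–Williams recurrence on squared dissimilarities, as
scipy's `linkage(..., "ward")` computes on a precomputed condensed distance)
with the dendrogram cut at a user-chosen k; a silhouette report over k is
emitted as an aid, but no automatic selection is performed because the
choice is a judgement about biological granularity. On inputs with tied
merge costs the Ward tree is not unique and the tie-break is
implementation-defined; oracle comparisons in the tests are restricted to
instances whose agglomeration has no tied decision. Block means per
(cell cluster × CpG cluster) are reported with the binomial standard error
over *cells* (the sampling unit), and chromatin-state enrichment of CpG
clusters uses the two-sided Fisher exact test with the sample odds ratio.
Methylation–expression correlation pairs each CpG with genes whose body
interval lies within 25 kb on the same chromosome and reports Pearson r
across shared cluster means (at least 3 clusters required).

## FNR-corrected pseudobulk inference

Within a cluster, detections follow
`n1 ~ Binomial(n0 + n1, (1 − p)·m)` with a uniform Beta(1, 1) prior on the
cluster methylation level m. The posterior density on [0, 1] is

    f(m) ∝ ((1 − p) m)^{n1} · (1 − (1 − p) m)^{n0},

a Beta(n1+1, n0+1) law in u = (1 − p)m truncated to [0, 1 − p]. The default
backend computes the posterior mean by adaptive quadrature (absolute and
relative tolerance 1e-6, density rescaled by its maximum for stability at
large counts) and the central 95% credible interval from a dense
cumulative-trapezoid grid refined around the mode — for a bounded scalar
parameter this is exact to tolerance and fully reproducible, which is why it
is preferred over the sampling-based inference that could equally be used; a
seeded random-walk Metropolis backend (with an initial-positive-sequence
effective-sample-size estimate) is provided for parity checks, and the
truncated-Beta closed form serves as an independent oracle in the tests.
Design points:

- the FPR is omitted from the observation model by default (it is an order
  of magnitude smaller than the dropout); an extended likelihood with
  detection probability `(1 − p)m + fpr(1 − m)` is available behind a flag;
- when the observed fraction exceeds 1 − p the likelihood peaks at m = 1;
  the posterior handles this without truncation and the estimate is flagged
  `saturated`;
- `p = 1` is rejected (nothing is observable); `n0 = n1 = 0` is rejected
  unless explicitly allowed, in which case the prior (mean 0.5) is returned;
- the model is fitted per amplicon × cluster with no pooling across
  amplicons, including amplicons with elevated FNR.

`n0` conflates "unmethylated" with "methylated but dropped"; that is exactly
the confound the `p_i` correction addresses, and no further missing-data
handling is applied.

## Protein normalization

Antibody-tag counts are normalized per cell by a centered log-ratio on
1 + count: `y_j = ln(1 + x_j) − mean_k ln(1 + x_k)` (rows sum to zero).
Several CLR dialects exist (pseudocount placement, geometric-mean base);
this one is stated explicitly so numeric differences against other
toolchains are explainable. Marker positivity is CLR strictly above 1, and
per-cluster marker summaries report mean ± 2·SE with singleton clusters
flagged.

## Problem sizes and numerical conventions

The test and acceptance runs use: 5,000 cells for error-rate recovery
(per-amplicon FNR within ±0.02 of truth at binomial precision), 2,000 cells
with 2,000 empty droplets and 200 discriminating amplicons for end-to-end
cluster recovery (ARI ≥ 0.9 at k = 3), 1,000-cell clusters for pseudobulk
recovery (±0.03 at true m = 0.8, FNR 0.2), 1,000 random sequences for the
scanner oracle and exhaustive agglomeration up to n = 10 for the Ward
oracle — sizes chosen to give the estimators their designed operating
conditions while keeping a full run in seconds. Coordinates are 0-based
half-open throughout (BED-compatible); MatrixMarket files are 1-based as the
format requires. All stochastic stages take explicit seeds; identical seeds
give byte-identical artifacts.

## Known limitations

- The elastic-net penalty mapping reproduces the glmnet objective but not
  glmnet's internal standardization; selected sets can differ at the margin
  for strongly unbalanced features.
- The FNR's dependence on sequencing depth and GC is reported as a
  diagnostic, not modelled.
- Doublet detection is out of scope (external tools); the simulator still
  emits doublets so downstream robustness can be exercised.
- Allele- and strand-specific methylation can bias pseudobulk estimates
  upward under the OR-detection rule; no allele-specific model is provided.
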