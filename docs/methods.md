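# Methods

## The association model

Each SNP–CpG pair within 50 kb (inclusive) on the same chromosome is
tested by ordinary least squares of the methylation level on the count of
reference alleles (0, 1, 2) plus covariates, per pair on complete cases.
The 50 kb window is inclusive at the boundary: a pair at exactly 50,000 bp
is tested. Two response scales are supported: the β-value itself (a
proportion, the scale effects are reported on) and the M-value
`log2(β/(1−β))` with β clamped to [10⁻⁶, 1−10⁻⁶], which is closer to
homoskedastic. t-statistics from the two scales agree to r > 0.99 on
significant pairs in simulation, so the β scale is the default.

Pairs whose complete-case residual degrees of freedom (n − 2 − #covariates)
fall below 30 are not tested at all; this keeps single-pair power floors
uniform and, importantly, the Holm family is then defined as exactly the
set of tests performed. Covariate columns that are constant on a pair's
complete cases are dropped without charging degrees of freedom. Two
degenerate cases are fixed by convention: a monomorphic genotype vector
yields no test (the pair is reported as filtered, reason "monomorphic"),
and a constant response yields slope 0, t = 0, p = 1 (the 0/0 ratio is
defined as 0) with the result flagged degenerate.

Holm's step-down adjustment is `adj_(i) = max_{j≤i} min(1, (m−j+1)·p_(j))`
over the ascending order statistics, returned in input order with stable
tie handling. It controls the family-wise error rate at 5% for independent
tests and is conservative under the positive dependence that linkage
disequilibrium induces; the null-simulation suite measures ~97% of
complete-null studies with zero discoveries at a 2,000-test family.

## Quality control

Filters run in a fixed order because the later statistics depend on the
retained sample set: methylation sample filters (detection call rate
< 90%; mean intensity < 50% of the experiment-wide sample mean or < 2,000
units), then masking of data points with detection p > 0.001, then PCA
outlier removal, then genotype filters (samples with > 5% missing calls;
SNP call rate < 95%; Hardy–Weinberg exact p < 10⁻⁵; MAF < 0.05 — all
strict inequalities, so a SNP at exactly MAF 0.05 survives), then
exclusion of CpG probes whose genomic footprint contains a known variant
(1-based inclusive at both ends). Every exclusion is logged with its
reason.

Hardy–Weinberg is tested with the exact conditional test: given the
allele counts, the p-value sums the probabilities of heterozygote counts
no more likely than the observed one. The implementation uses log-gamma
arithmetic with an exact-rational enumeration oracle in the tests
(exhaustively verified for every table with n ≤ 50).

PCA outliers are samples whose distance from the origin in the PC1–PC2
plane (β-values, mean-imputed per CpG for the decomposition only)
exceeds 2.5 standard deviations of the centered PC scores — i.e. 2.5
times the root-mean-square distance. Scaling the cut by the standard
deviation of the *distances* instead would flag ~26% of perfectly typical
samples, because in two dimensions distances concentrate tightly around
their mean; the RMS form flags ~0.2% of null samples and reliably catches
gross shifts. Removal is single-pass (no re-iteration after removal).
A geometric consequence worth knowing: the cut scales with the outliers'
own contribution to the spread, so a coherent block of more than roughly
a sixth of the samples cannot be flagged in one pass; the synthetic
defaults keep outlier fractions at or below 10% per cohort.

## Cross-cohort statistics

Overlap tables restrict all cohorts to the SNP–CpG pairs tested in every
cohort (Holm adjustment is *not* redone after restriction — each cohort's
correction covers the tests it performed). Percent cells use the column
cohort's meQTL count as denominator, rounding half away from zero to one
decimal. The independence test for each cohort pair is a one-sided Fisher
exact test on {both, i-only, j-only, neither} over the common universe,
computed as a hypergeometric upper tail in log space (one log-gamma
evaluation plus a pmf-ratio recurrence), so p-values below the
double-precision floor remain representable as log₁₀ p; the test suite
verifies agreement with exact rational enumeration for every table with
total ≤ 60.

Sign concordance drops rows containing a zero (signless) t-statistic,
takes `pᵢ` = fraction of positive t in cohort *i*, and compares observed
agreement with the Poisson-binomial chance law of the number of positive
signs S: all-same has probability `∏pᵢ + ∏(1−pᵢ)`; at-least-m-same is
P(S ≥ m or S ≤ k−m), computed from the exact pmf by convolution (the two
events overlap when m ≤ k/2, which the direct pmf summation handles
without double counting). Observed-vs-chance comparisons use one-sided
binomial tests reported as log₁₀ p.

The subject-partition check splits the common subjects of two datasets at
random into halves A and B and rescans each tissue in each half: overlap
between tissue X in half A and tissue Y in half B involves disjoint
subjects, so persistent cross-tissue overlap there cannot be an artifact
of shared individuals. Halved samples use a reduced residual-df floor
(default 10) since each scan has half the subjects.

LD pruning slides a 50-SNP window in steps of 5 and removes the later SNP
(by position, then ID) of any retained pair with genotype r² > 0.05. A
window can alternatively be a span in bp (`window_unit="bp"`); 50
consecutive SNPs is the default because pairwise pruning on a SNP-count
window is the standard idiom for producing a roughly independent SNP set.
Hierarchical clustering of the pairs × cohorts t-matrix (missing t set
to 0) uses Euclidean distance with average linkage; scipy's
agglomerative implementation breaks ties by input index, making the tree
deterministic for a fixed row order.

## Enrichment

MAF bins are `floor(MAF/0.025)` with MAF = 0.5 assigned to the top bin
(20 bins over (0, 0.5]); the bin boundary computation guards against
float division (0.075/0.025 < 3 in binary). Each random set draws,
without replacement and per bin, exactly the meQTL set's bin count from
the full analyzed universe — the meQTL SNPs themselves remain eligible,
matching sampling "from the full set analyzed". The empirical p-value is
the fraction of random sets overlapping the target at least as much as
observed; with zero exceedances the result reports as the bound
`p < 1/N`, and a (count+1)/(N+1) corrected value is also provided for
downstream use since an exact zero is unusable in, e.g., meta-analysis.
Defaults are 10,000 resamples for GWAS/meQTL/eQTL targets and 1,000 for
small annotation sets. Binning is per cohort (each cohort's own allele
frequencies), so the same SNP can sit in different bins in different
cohorts.

## The synthetic study generator

The generator produces the structure the analysis assumes, not realistic
sequence: cohorts share one synthetic chromosome's SNP and CpG positions
but differ in allele frequencies, LD, baselines and nuisance structure.

* **Genotypes.** Per-SNP minor allele frequencies are drawn uniformly
  from the cohort's MAF range once per *ancestry group*, so same-group
  cohorts share frequencies. Each haplotype carries a latent uniform that
  restarts at LD-block boundaries and refreshes with probability 0.1 per
  SNP inside a block; the allele is the indicator that the latent falls
  below the alt-allele frequency. The two haplotypes are independent, so
  marginal allele frequencies are exact and Hardy–Weinberg holds by
  construction, while within-block r² decays geometrically with SNP
  distance. Block length 1 gives fully independent SNPs. The default
  study gives the two African-American-like cohorts blocks of 4 SNPs and
  the Caucasian-like cohorts blocks of 10 — enough to reproduce the
  detection-power gap that shorter LD causes at matched sample size.
* **Methylation.** Baselines are logit-normal per CpG (cohort-level mean
  shift SD 0.3; CpG-level logit SD 0.8, narrowed to 0.5 for CpGs carrying
  planted effects so the effect stays in the β-scale's responsive
  mid-range), with per-sample logit noise SD 0.3 — about 0.075 SD on the
  β scale at mid-range, typical of array replicates. Planted cis effects
  add `sign · 0.1 · (allele count)` on the β scale before clamping to
  [0.01, 0.99]; a pre-build simulation showed the clamp attenuates the
  recovered slope by under 3% across baseline spreads, and the scan
  recovers the planted slope to within ~1% with ~95% Holm power at
  n = 100. Effects can be shared by all cohorts, by the brain-like
  subset, or private to one cohort (the default mixes the three kinds
  equally, mirroring partially-shared regulatory architecture).
* **Nuisance structure.** Brain-like cohorts get 3 hybridization batches
  with per-(batch, CpG) β offsets of SD 0.02 and indicator covariates in
  the scan; outlier samples receive a global ±0.25 β shift with random
  direction (detectable by the PCA rule by construction); detection
  failures occur at rate 0.005 and mask their data points in QC.
* **Scale.** Default sizes (1,000 SNPs, 250 CpGs, 5 Mb, 7 cohorts of
  87–125) give ~4,800 cis tests per cohort and run end to end in a few
  seconds — the study design at desk scale. The generator is a pure
  function of its config including the seed; per-stage seeds derive from
  the run seed via `SeedSequence(seed, spawn_key=(stage,))`.

What passing tests on this generator do **not** show: robustness to
cell-type composition differences (mixed tissues are simulated only as
baseline shifts), to probe cross-hybridization, to genotyping error or
imputation uncertainty (calls are hard and error-free), or to fine-scale
recombination structure (LD blocks are rectangular). Conclusions about
real arrays need the QC cascade precisely because those artifacts exist
there.

## Numerical choices and limitations

* All output floats serialize with 10 significant digits; result rows
  sort by (snp_id, cpg_id) so reruns are byte-identical.
* Missing genotypes are NaN in a float matrix (distinct from the valid
  code 0); analysis is complete-case per pair, with no imputation.
* The Fisher tail, HWE test and Holm adjustment each have an independent
  oracle in the test suite (rational enumeration or statsmodels); the
  per-pair OLS is checked against statsmodels OLS on random instances.
* The empirical enrichment p is granular at 1/N; calibration is verified
  at N = 1,000 over 200 replicate null tests.
* Known limitation: with hard 0/1/2 calls the pipeline cannot consume
  fractional imputation dosages; imputed data must be thresholded to
  best-guess genotypes upstream.
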