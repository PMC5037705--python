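# Methods

This note records the models, defaults and numerical choices behind
`metaboqtl`, and what the synthetic study does and does not establish.

## Study model

The pipeline treats a quantitative target trait (drip loss, in %) as the
downstream readout of latent metabolic pathway activities, which are in
turn partly genetic. Three layers are modelled explicitly:

1. **Genotypes.** Biallelic autosomal SNPs, dosage-coded as counts of the
   minor allele, with missing calls allowed.
2. **Metabotypes.** Quantified metabolite/protein abundances, grouped into
   a pathway catalog; membership may overlap.
3. **Phenotype.** The target trait plus two nuisance variables, slaughter
   date (categorical) and slaughter weight (kg).

The phenotype model is `y = mu + SD_j + beta_s*SW + beta_g*g + e`. It is
operationalized in two stages: the nuisance part (date + centered weight)
is fitted once per phenotype by OLS, and the genetic term is tested per
SNP on the residuals by the PC-corrected score test. Centering the weight
covariate makes the intercept interpretable and leaves residuals
unchanged.

## Synthetic data generator

`simdata` emulates the statistical structure of a ~97-animal pig study.

- **Population structure.** A real F2 reciprocal cross is simplified to a
  two-subpopulation model: per SNP a base frequency p ~ Beta(2,2) rescaled
  to [0.05, 0.95] is split into founder frequencies p ± divergence/2
  (clipped to [0.01, 0.99]); samples are assigned half/half and dosages
  drawn Binomial(2, p_subpop). This reproduces the one property the
  pipeline needs — PC-detectable stratification of tunable strength —
  without pedigree bookkeeping. At divergence 0 the subpopulations are
  exactly exchangeable.
- **Causal chain.** Each of `n_causal_snps` SNPs (default 3) drives one
  pathway's latent activity `a = effect*g + N(0, activity_noise_sd)`;
  members of that pathway read `loading*a` plus independent noise, and the
  trait reads `weight_p*a` per causal pathway plus date, weight and
  residual terms. Effect magnitudes are fixed at `snp_effect_sd` /
  `pathway_weight_sd` with random signs rather than drawn from a normal:
  the generator's role is to define controlled study conditions, and a
  zero-centered draw would make the planted signal strength itself a
  random variable. Causal SNPs are drawn among SNPs with counted-allele
  frequency in [0.3, 0.7] so that marker QC cannot silently delete the
  planted signal.
- **Defaults.** n=97 samples, 45,000 SNPs on 18 autosomes of 150 Mb, 128
  metabolites + 35 proteins in 219 pathways of 2–10 members, divergence
  0.15, six slaughter dates with N(0, 0.3%) shifts, weight effect 0.05
  %/kg on N(86.5, 5) kg weights clipped to [73, 102], residual sd 0.8%,
  1% missing genotypes. With effect and loading 1, each causal SNP
  contributes ~0.47 of ~2.9 total trait variance units, i.e. ~15–16% —
  the regime in which single-SNP mapping at n=97 is borderline, which is
  exactly where the intermediate-phenotype route should (and does) help.
- **Trait range.** Realized traits are affinely mapped into the plausible
  drip-loss band [0.4, 5.3]% only when they stray outside it; the affine
  coefficients are stored in the truth ledger so recovery tests can
  compare estimates against the scaled truth.
- **Annotation.** The toy GFF3 places one gene over each causal SNP (the
  SNP falls in an intron of a 100-kb gene with three exons) plus 30
  distractor genes, making gene-level recovery testable end to end.

What the generator does *not* emulate: linkage disequilibrium between
SNPs (markers are independent given ancestry), pedigree relatedness,
mass-spectrometric measurement artifacts (batch effects, censoring,
heteroscedastic noise), and non-MCAR genotype missingness. Passing tests
therefore demonstrate correctness of the statistical machinery under the
model's assumptions, not robustness to real-data pathologies.

## Marker quality control

SNPs are dropped when MAF < 1%, call rate < 95%, or HWE p < 1e-3 — the
thresholds are exclusive as written, so equality survives. The HWE test is
the 1-df Pearson chi-square without continuity correction by default; an
exact conditional mid-p test is available (`hwe_method="exact"`) since at
MAF near the 1% boundary with n=97 the asymptotic test is approximate. No
sample-level QC is applied. Dosage coding counts the minor allele; ties at
frequency 0.5 resolve to the alphabetically later allele, which makes the
PED round trip byte-stable.

## Enrichment

The MR-GSE statistic ranks components by correlation and applies a
one-sided Wilcoxon rank-sum test of "members rank higher". The default
ranking uses |r| ("mixed" mode): enriched pathways may contain both
positively and negatively correlated members, and a signed mode is exposed
for directional questions. Exact p-values are computed by enumerating all
C(m, k) member placements when that count is at most 1e5 (the p-value is
the proportion of placements reaching the observed rank-sum, so it is
never 0); larger sets use the normal approximation with tie correction and
a 0.5 continuity correction. The two routes agree within 0.01 for sets of
3+ members; at k=2 the rank-sum distribution is too discrete for the
asymptotic tail to track it more closely than ~0.01. No multiple-testing
correction is applied across pathways — the p <= 0.05 gate is a screening
device, not an inference, and its output is only used to choose which
traits to map.

## Association scan

- **Kinship.** Allele-frequency-standardized covariance, averaged
  pairwise-complete over SNPs where both samples are called; monomorphic
  SNPs are skipped and counted.
- **PCs.** Eigenvectors of the double-centered kinship matrix, eigenvalues
  descending, each vector's sign fixed by making its largest-magnitude
  entry positive (determinism across BLAS implementations).
- **Score test.** Missing dosages are mean-imputed per SNP; trait and
  dosage are residualized on [1, PC_1..PC_k] via a QR factorization; chi2
  = (n - k - 1) r^2. This equals (n - k - 1) times the partial R^2 of an
  explicit OLS with PC covariates (checked to 1e-8 in tests). The allele
  substitution effect and its SE come from the same residual regression.
  SNPs whose dosage residual variance is numerically zero (relative
  tolerance 1e-12) are skipped and logged.
- **PC count.** k scans from 1 to 10; the k with |lambda - 1| smallest
  wins, ties to smaller k; lambda at k=0 is logged for reference. The
  denominator 0.4549 is the chi-square(1) median to four decimals.
- **q-values.** Storey's procedure with pi0 estimated by a cubic
  polynomial fit to pi0(lambda) over lambda = 0.05..0.95 evaluated at the
  grid maximum, bounded to [1/m, 1]; for short p-vectors (m < 100) or
  degenerate profiles the raw estimate at the largest lambda is used
  instead of the smoother. Setting pi0 = 1 reproduces Benjamini–Hochberg
  exactly, which is the test oracle. q-values are computed per trait scan:
  each trait is its own testing universe.
- **Explained variance.** Var% = 100*chi2/(n-2+chi2). Note this formula
  and published per-SNP variance tables in this literature do not always
  agree (the formula gives 14.45% for chi2 = 16.05 at n = 97, where a
  published value of 8.82% exists); the implementation follows the formula
  literally.
- **Empirical p.** An optional permutation mode (trait residual permuted
  across samples, per-SNP exceedance counts with the +1 correction) exists
  for users who prefer empirical to asymptotic p-values; q-values are
  computed on asymptotic p by default.

## QTL regions and candidate genes

Region condensation is single-linkage chaining: consecutive significant
SNPs on a chromosome closer than 1 Mb share a region. The published
"similar MAF / effect / variance" language around this rule carries no
thresholds, so the implemented rule is distance-only; region reports carry
the member SNPs' statistics so heterogeneity is visible. Overlap detection
is exact interval intersection (QTL level) and shared-significant-id
matching (SNP level).

Gene windowing measures the distance from the SNP to the nearest gene-span
edge and includes genes at exactly 1,000,000 bp. Location classes are
exonic, intronic, genic-unresolved (inside a span with no exon records —
the honest label when annotations lack exon structure) and within-1Mb.
Candidate selection ranks each trait's significant SNPs by (p, q,
position), keeps the Top 10 (metabotypes) or Top 25 (target trait), and
requires an in-gene location. All coordinates are 1-based inclusive;
strand is ignored for distance and containment.

## Pipeline

One YAML config drives simulate → qc → adjust → enrich → gwas → annotate;
all randomness flows from a single seed, every output file is SHA-256
hashed into a manifest, and identical configs reproduce identical
manifests. The run log records the selected PC count and lambda per trait.
Disabling the enrichment gate scans the target trait only.

## Problem sizes and test design

Tests and the acceptance script run the generator at 300–10,000 SNPs
rather than the 45,000-SNP default: the statistical properties being
checked (calibration, lambda correction, recovery rates) are
per-SNP/per-trait properties whose verification does not sharpen with
marker count, and the smaller panels keep the full suite fast and
deterministic. Recovery checks use 2,000-SNP panels with three ~15%
causal SNPs at n=97 over 10 fixed seeds; the stratified-null lambda check
uses 10,000 SNPs at divergence 0.3 over 10 seeds. Monte-Carlo assertions
use 99% binomial intervals and fixed seeds throughout.

## Known limitations

- Single-marker tests only; no mixed-model GRM correction, no LD-aware
  clumping, no haplotype or X-chromosome handling.
- The stratification model is a two-population split; gradients or family
  structure may need more PCs than the 1–10 scan provides.
- Exact MR-GSE enumeration is combinatorial; very large member sets fall
  back to the asymptotic approximation.
- With exon-less annotations the pipeline can only assign
  "genic-unresolved", never intronic/exonic — reports state the class
  explicitly rather than guessing.
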