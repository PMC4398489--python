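# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `feednet`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Phenotype construction

RFI is the residual of an OLS regression of daily energy intake (dEI, MJ
ME/day) on average daily gain (ADG, kg/day) and metabolic mid-weight (MMWT,
kg^0.75) over a 92-day test window (month 6 to month 9 of age). Energy
intake is computed from feed masses at 9.0 MJ ME/kg DM for hay and 11.3 for
concentrate. The fit is plain OLS without fixed effects: year and season
enter later as fixed effects of the association model, not the RFI
regression. Animals missing any of dEI/ADG/MMWT are excluded from the fit
and reported, never imputed. By construction the residuals sum to zero and
are orthogonal to both regressors (asserted at 1e-8 relative tolerance); a
reported cohort-average RFI that differs slightly from zero can only arise
from rounding or post-fit exclusions, and this implementation reports the
exact-zero-mean residuals. An exact-zero RFI is labelled "boundary" rather
than forced into the efficient/inefficient dichotomy, which is otherwise
strictly by sign. Season is the calendar class (May–October vs
November–April) holding the majority of test days, ties going to season 1.

## Genotype QC

Retained SNPs need call frequency > 0.85 (strict), MAF > 0.01 (strict,
computed on non-missing calls), and an autosomal location; retained samples
need call rate > 0.98 (strict). Filters run in the order SNP rules →
sample call rate; call frequencies are computed over the samples present in
the matrix handed in. Hardy–Weinberg disequilibrium (1-df chi-square) is a
report-only diagnostic because in the source workflow it triggered manual
cluster review, not removal; monomorphic SNPs get p = 1 by convention. The
0.98 threshold exists twice in the original protocol (SNP-cluster re-review
trigger and sample call rate); both are exposed as separate parameters.

## Mixed-model association

The animal model per SNP is y = Xφ + Zg + u + e with u ~ N(0, A σ²_u) and
Z ∈ {−1, 0, +1}. **A** is built by the tabular recursion (founders 1 on the
diagonal; a(i,j) = ½[a(sire,j) + a(dam,j)]; diagonal 1 + ½a(sire,dam)),
validated in tests against textbook cases and a gene-dropping Monte Carlo
oracle.

Estimation is maximum likelihood via the eigendecomposition A = U D U′: in
the rotated basis the covariance is diagonal, so the profile likelihood over
the variance ratio λ = σ²_u/σ²_e is a one-dimensional bounded optimization
(on log(1+λ), λ ∈ [0, 1e4], with an explicit boundary check at λ = 0), and
each SNP test is a weighted least-squares fit. ML rather than REML is used
because likelihood-ratio tests of fixed effects require it. The LRT is
chi-square with 1 df (one added covariate); the same holds for the
interaction contrast.

Per-trait scans hold λ at the null-model estimate for every SNP test (the
standard approximation; an exact per-SNP re-estimation mode sits behind
`reoptimize=True`). The interaction test is the exception: its variance
ratio is re-estimated under the two-SNP base model, because gene-dropped
genotypes are themselves family-structured and major additive QTL would
otherwise inflate the no-SNP polygenic estimate and misweight the contrast.
Standard errors use the degree-of-freedom-corrected residual variance from
the weighted fit. Missing genotypes are mean-imputed on the {−1,0,1} scale
for the tested SNP only; monomorphic or collinear covariates are flagged
untestable with p = 1 rather than dropped silently. With A = I the
σ²_u/σ²_e split is unidentifiable; the model flags this and reduces exactly
to OLS (tested against the OLS F-test to 1e-6).

No multiple-testing correction is applied anywhere in the GWAS: the AWM
deliberately consumes nominal p ≤ 0.05.

## AWM

"Normalizing the SNP effects" is implemented as signed t-values (effect/SE)
followed by per-trait-column z-scaling; both the scaled (default) and raw-t
modes are exposed. Key-trait selection is inclusive (p ≤ 0.05). A_P is kept
fractional and the rescue comparison ("more than A_P" supportive
associations, at the same p ≤ 0.05 threshold) is strict on the fractional
value. The gene-distance rule is strict (< 2,500 bp; inside a gene counts
as distance 0); a SNP reachable by several genes goes to the nearest one,
ties to the lower start coordinate. Per-gene deduplication keeps the SNP
associated with the most key+supportive traits, ties broken by smaller
key-trait p, then lower position. Coordinates are 1-based inclusive
internally; BED input (0-based half-open) is converted at the boundary and
round-trip tested. Trait columns are clustered by average linkage on
1 − Pearson correlation with deterministic (optimal) leaf ordering.

## PCIT

For each trio the three first-order partial correlations
r_xy.z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) are computed and the trio
tolerance is the mean partial/direct ratio; the x–y association is discarded
if for some z both |r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|. Ratio terms with
an exactly zero direct correlation are omitted from the mean rather than
propagating infinities; trios with |r| = 1 in a conditioning pair are
skipped and counted. Correlations are clamped to ±(1 − 1e-12) before the
partial-correlation formula. The production implementation loops over the
conditioning gene and vectorises the x–y plane (O(n³) flops, O(n²) memory;
1,000 genes run on one CPU); an independently coded scalar triple-loop
reference exists solely as a cross-check, and equality of the two is
asserted over random instances in tests and in the acceptance script.

Note a consequence of the tolerance rule worth knowing: an edge with
r_xy = r_xz·r_yz (fully explained by z) is discarded for moderate
conditioning correlations but can survive when both |r_xz| and |r_yz| are
very high, because the zero partial/direct ratio drags ε down. Edge
extraction requires PCIT significance AND |r| ≥ 0.80 (inclusive by default;
a strict-inequality flag exists because the source text uses both
phrasings). The reported edge weight is the direct correlation. With only
14 trait columns, gene-row correlations are intrinsically high-variance;
this is faithful to the design rather than something to smooth away.

## Network topology and the null comparison

Networks are undirected simple graphs; isolated genes are not nodes; hubs
are genes with degree ≥ 80 (configurable), and the low-connectivity summary
counts degree ≤ 10. Density is 100·edges/(n(n−1)/2). The null comparison
permutes the AWM independently within each trait column — preserving each
trait's marginal effect distribution while destroying cross-trait structure
— and re-applies the identical PCIT → |PC| → network pipeline to each of
10 replicates (a whole-matrix shuffle is available behind a flag).
Identical filtering for observed and random matrices is deliberate:
anything else would invalidate the comparison.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
bovine genomics in detail:

* **Pedigree**: founders → F1 → F2, F1 of alternating sex, each F2 with an
  F1 sire and a different F1 dam. Study-scale defaults: 40 founders, 40 F1,
  200 F2 (the study genotyped 176 of 237 F2 bulls from a 933-member,
  three-generation pedigree).
* **Genotypes**: unlinked biallelic SNPs; founder allele frequencies uniform
  on the MAF range (default 0.10–0.50), founder genotypes at Hardy–Weinberg
  proportions, Mendelian gene-dropping below, {−1,0,+1} coding, optional
  missingness. Unlinked is a deliberate simplification: the analysis
  operates on single-SNP effects and AWM/PCIT never model LD.
* **Traits**: 13 latent traits (RFI, ADG, 11 metabolites) built as fixed
  effects + QTL + polygenic + residual. Polygenic values are drawn through
  the Cholesky factor of the pedigree relationship matrix, matching the
  GWAS model's u ~ N(0, Aσ²_u) exactly. The combined polygenic+residual
  part carries the published phenotypic correlation matrix of the 14
  analysis traits (transcribed at printed precision; pairs involving ADG,
  absent from that table, default to zero; the matrix is eigenvalue-clipped
  to the nearest PSD correlation matrix if rounding made it indefinite).
  Trait scales (means, SDs) are the published descriptive statistics;
  metabolites in μM, weights in kg, energies in MJ ME. Realized QTL variance
  is deducted from the target SD so totals stay on scale.
* **QTL**: two default loci mimicking the NCAPG I442M and GDF8 Q204X
  variants with the published allele-substitution effects (RFI −2.18 /
  −3.30, ADG +0.08 / +0.06, Arg +9.03 / −6.20, C0 +0.11 / −0.73).
* **Derived records**: dEI = 4.0 + 25.0·ADG + 0.5·MMWT + RFI (coefficients
  chosen so the derived dEI and FCR cohort statistics land inside the
  published ranges), feed masses back-computed from dEI at the 1:3
  hay:concentrate ratio, body weights from a N(230, 15²) start plus gain.
  Feeding records, weights and dEI are therefore mutually consistent by
  construction, and the phenotype engine recovers them exactly.
* **Heritabilities** were not reported for the source population; the
  default 0.30 sits in the cited literature range for RFI (0.16–0.43) and
  is configurable per trait.
* **Fixed effects** default to mild level effects (±0.1 SD across years,
  ±0.05 SD across measurement days) so that trait correlations are not
  visibly diluted; birth dates are uniform over the year and season follows
  the calendar rule.

What the generator does **not** emulate — LD structure, selection,
genotyping-intensity artifacts, non-Gaussian metabolite distributions,
sex chromosomes — bounds what passing tests show: they validate the
statistical machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Problem sizes and calibration studies

The shipped studies use sizes chosen to make sampling noise small relative
to the quantities asserted: null calibration uses 5,000 SNP-trait tests on
400 animals with zero heritability and no QTL; effect recovery re-estimates
a +0.08 kg/day ADG QTL in 100 replicates of 2,000 animals (pedigree,
relationship matrix and its decompositions are computed once and shared
across replicates); interaction calibration uses 400 replicates of 500
animals with two additive loci; the null-network contrast uses a 300-gene
AWM in 10 blocks of 30 (within-block row correlation ≈ 0.94). Ten blocks
rather than a few: with very few blocks the column marginals are strongly
multimodal, and within-column permutation then produces spurious edges from
chance block-label alignment, which would defeat the contrast the control
is meant to show. The full pipeline demonstration runs 200 animals × 3,000
SNPs × 14 traits.

Two calibration facts a user should know. First, a ±2·SE interval has
95.45% nominal coverage, so "at least 95 of 100 replicates" is expected to
fail by chance roughly one run in three even for a perfectly calibrated
estimator; the z-scores (estimate − truth)/SE in the recovery study are the
better diagnostic and are checked to be mean ≈ 0, SD ≈ 1. Second, the ML
estimate of the variance ratio σ²_u/σ²_e on ~500 animals has wide sampling
spread (roughly 12% of replicates fall outside a factor of two of the truth
for family designs of that size) while remaining median-unbiased; tests
assert accordingly.

## Numerical choices

Eigendecompositions clip tiny negative eigenvalues at zero; relationship
submatrices get a 1e-8 ridge before Cholesky factorisation; a non-PSD
submatrix raises an error that names the ridge remedy. The λ optimizer is
scalar bounded search with xatol 1e-8. Weighted least squares uses
`lstsq` on the normal equations of the rotated design. Degenerate inputs
fail loudly: zero-variance traits, collinear RFI regressors (the offending
column is named), constant AWM columns/rows, empty gene sets, self-loop
edges.

## Interfaces

Genotypes: VCF v4.2 (read via cyvcf2; written by a minimal GT-only writer)
or a TSV dialect; phenotypes and pedigrees as TSV (missing = empty field;
parent 0 = unknown); annotation as BED or GFF3 (gene features); AWM as a
tab-delimited gene × trait matrix; edges as a 3-column TSV loadable by
Cytoscape; networks additionally as GraphML. The pipeline runner writes a
JSON manifest with input hashes, parameters, seed and version, and
identical configurations produce byte-identical AWM and edge artifacts
(tested). The CLI (`feednet`) exposes simulate | qc | phenotypes | gwas |
awm | pcit | network | nullcheck | run as thin wrappers over the library.

## Known limitations

Variance components are reported from ML, which is downward-biased in small
samples relative to REML; the LRT requires ML, so that is the default.
Two-SNP and interaction models are targeted (candidate pairs), not scanned
genome-wide. The PCIT tolerance rule's behaviour at extreme conditioning
correlations (see above) is inherited from the algorithm, not adjusted.
Gene mapping assigns each SNP to a single nearest gene; overlapping-gene
ambiguity beyond the documented tie-break is not modelled.
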