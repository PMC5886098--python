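# Methods

This note documents the statistical models implemented in
`crosstrait`, the synthetic-data generator that stands in for
access-controlled consortium data, the numerical choices made where
the design was open, and the limitations of each.

## Summary-statistics model and harmonisation

All analyses operate on per-variant association summaries: effect
allele, other allele, additive-scale effect β (log-odds for binary
traits, per-SD for quantitative), its standard error, Z = β/se, a
two-sided p-value and a sample size n.  Odds ratios are converted to
log-odds at read time so a single effect scale flows through the
package.  For case-control studies without a per-SNP n, the effective
sample size 4/(1/n_cases + 1/n_controls) is used; it is the n under
which z = β√n holds on the standardised scale and is what the
cross-phenotype statistics weight by.

Harmonisation restricts a pair of studies to shared variant ids and
re-orients the second study's alleles to the first: swapped alleles
negate β and Z and complement the allele frequency; strand
relabellings (A↔T, C↔G across the whole record) are reconciled
without a sign change; pairs that match under neither reading are
dropped and tallied.  Strand-ambiguous A/T and C/G variants are
dropped by default — with only summary data their orientation cannot
be resolved, and silently keeping them risks sign errors, so the
conservative standard is the default.  Variant identity is the rsID;
coordinates are carried through untouched (no liftover) and used only
for LD-block assignment and reporting.

If a stored p-value disagrees with the two-sided normal tail of the
stored Z by more than 10⁻⁶ relative, the p is recomputed from Z and
the event tallied; Z (or β/se, which takes precedence) is treated as
the primary datum.

## LD model

Linkage disequilibrium is represented as approximately independent
blocks with a signed correlation matrix per block; cross-block LD is
defined to be exactly zero.  That definition is what "approximately
independent" licenses, and it makes pruning, the permutation engine,
colocalisation and the simulator block-separable.  LD scores are
l_j = Σ_k r²_jk over the block, self included, with no finite-sample
bias correction: the reference LD here is the exact population LD of
the simulation.  For real reference panels estimated from finite
samples, the usual (r²(n−2)+1)/(n−1)-type adjustment would be needed;
this is a known limitation of using the package on external LD.

Block files follow the BED convention (0-based half-open, so a
variant at the boundary position belongs to the following block);
reports print 1-based inclusive coordinates.

## Synthetic data generator

The generator emulates the paired OA-like/BMD-like design this
package targets.  Within a block with LD matrix R, observed Z-vectors
are

    Z_t = R λ_t + ε_t,   λ_t = √n_t β_t,

with (ε₁, ε₂) jointly normal, Cov(ε_t) = R and Cov(ε₁, ε₂) = c·R,
where c is the sample-overlap correlation.  Noise is generated from
the symmetric PSD square root of R (computed once per block and
memoised) as ε₁ = S u, ε₂ = S(c u + √(1−c²) v) with u, v iid
standard normal, which yields the target covariance exactly.

Two effect models are provided:

* **Polygenic**: β drawn per SNP from a bivariate normal with
  variances h²_i/m and covariance r_g √(h²₁h²₂)/m.  This produces
  E[χ²_j] = 1 + n h² l_j/m and E[z₁ⱼz₂ⱼ] = c + √(n₁n₂) ρ_g l_j/m —
  exactly the regressions LD score regression fits.
* **Regional scenarios**: sparse non-centralities matching the five
  colocalisation hypotheses (no causal SNP; one causal SNP in one
  trait; the same SNP in both; two distinct SNPs), propagated through
  R.

Default study conditions: m = 20,000 SNPs in blocks of 50;
n₁ = 17,716 (the effective n of 7,410 cases / 11,009 controls),
n₂ = 31,800; h² = 0.20/0.25 (plausible common-variant heritabilities
for a binary joint phenotype and a quantitative bone phenotype);
r_g = 0.18; overlap c = 0.05 (the emulated design excludes the
directly shared cohorts, leaving a small residual overlap).  Per-block
AR(1) correlation cycles deterministically over [0, 0.9]: the genome
mixes high- and low-LD regions, and that between-SNP variation in LD
score is precisely what identifies the LD-score regression slope — a
panel with homogeneous LD would leave the regressor nearly constant
and the estimator ill-conditioned.

All randomness flows from one seed through per-block spawned
substreams, so outputs are bit-identical for a fixed seed and panel.

What the generator does **not** model: allele-frequency-dependent
effect sizes, imputation error (info is left blank), population
structure or relatedness, sex chromosomes, and LD between blocks.
Passing tests therefore demonstrate correctness of the estimators
under the stated sampling model, not robustness to those real-data
complications.

## LD score regression

The univariate fit regresses χ² on x_j = n_j l_j/m, so the slope is
h² directly; the bivariate fit regresses z₁z₂ on √(n₁n₂) l_j/m, so
the slope is the genetic covariance and the intercept estimates the
overlap term c.  Heteroskedasticity weights 1/(2(1+n h² l/m)²)
(univariate) and 1/((1+n₁h₁²l/m)(1+n₂h₂²l/m) + (√(n₁n₂)ρ_g l/m + c)²)
(bivariate) are iterated twice from an OLS start; weights depend on
the regressor only, so they affect efficiency, not unbiasedness.
Standard errors come from a delete-one jackknife over 200 contiguous
SNP blocks (configurable), with the same block partition deleted from
all three regressions so the r_g standard error reflects their joint
variability; p(r_g) is the two-sided normal tail of r̂_g/se.  If
either ĥ² ≤ 0, r_g is undefined and reported as missing rather than
clamped.  No constrained-intercept mode is offered: overlap is
modelled, not assumed away.  When info/eaf columns are present,
standard hygiene filters (info > 0.9, 0.01 < eaf < 0.99) apply before
regression; synthetic data carries no info so the filters are inert
there.

Note that the univariate and bivariate regressions use slightly
different weights, so the self-pair r̂_g(a, a) equals 1 only to about
10⁻³, not machine precision.

## Sample-overlap estimation

Two estimators of the scalar overlap correlation c are provided: the
bivariate LDSC cross intercept, and the Pearson correlation of the
two traits' Z-scores over independent null SNPs (r² < 0.2, |z| < 1.96
in both).  The second is the default wherever a scalar c is needed
(colocalisation, the CPASSOC correlation matrix).

Two corrections matter here and are deliberate design choices:

1. **Selection**: the independent panel is pruned in genomic order, a
   data-independent selection.  Pruning in p-value order would keep
   the largest-|z| member of each LD clump and bias the correlation
   upward by a few hundredths.
2. **Truncation**: restricting to |z| < 1.96 in both traits
   attenuates the correlation of a bivariate normal (a true c = 0.3
   appears as ≈ 0.235).  The raw correlation is therefore
   de-attenuated by numerically inverting the truncated-bivariate-
   normal correlation map (Gauss-Legendre quadrature of the doubly
   truncated moments, Brent root-finding).  Observed correlations
   beyond the attainable range clip to ±1.

## Overlap analysis

Pruning is the greedy clump on the first (OA-role) trait's p-values:
visit variants in ascending p (ties by chromosome, position, id),
keep a variant iff its r² with every kept variant of its block is
≤ 0.05.  Because cross-block r² is zero, the global greedy pass
decomposes into independent per-block passes, which is how it is
implemented; a brute-force re-execution of the sorted definition is
kept as a test oracle.

At each of the ten thresholds (0.5 … 5×10⁻⁴) a 2×2 table of strict
"p < t" indicators is formed and the Pearson chi-square (no
continuity correction) computed; a zero margin leaves the chi-square
undefined and the analytic p missing.  The permutation null shuffles
the second trait's p-values, one shuffle per replicate shared across
all thresholds (preserving cross-threshold dependence).  A
permutation leaves both margins fixed, so the chi-square of a
permuted table is the closed form in the both-below count n₁₁ —
algebraically identical to re-running the test — and the engine
evaluates that.  The empirical p uses the add-one estimator
(r+1)/(N+1), counting permutations whose chi-square is at least the
observed one; each result also records whether the observed overlap
exceeds its expectation, so an excess and a deficit are never
conflated in reports.  (Counting only direction-matched exceedances
would double the null rejection rate of the nominal level, which is
why the direction is reported rather than folded into the p-value.)
When the observed chi-square is undefined, p_perm is reported as 1.

Candidate selection for replication unions (i) all variants below
P_t = 0.005 in both traits of any pruned comparison and (ii) the top
SNP per trait of every colocalisation-flagged region, deduplicated
and sorted.

## Colocalisation

The regional model is the standard single-causal-variant-per-trait
frame: per SNP j, evidence for association is the Wakefield
approximate Bayes factor with effect-prior variance W (default 0.04
on the log-odds / per-SD scale); per-SNP priors are p₁ = p₂ = 10⁻⁴
(one-trait causal) and p₁₂ = 10⁻⁵ (shared causal) — field-standard
defaults, fully exposed in configuration since the original analysis
does not print its constants.  Hypothesis evidence is assembled in
log space:

    H1 ∝ p₁ Σⱼ ABF1ⱼ      H2 ∝ p₂ Σⱼ ABF2ⱼ
    H3 ∝ p₁₂ Σⱼ jointABFⱼ  H4 ∝ p₁p₂ Σⱼ≠ₖ ABF1ⱼ ABF2ₖ

against an H0 baseline of 1, normalised by log-sum-exp; a single-SNP
region has PP(H4) = 0 structurally.  The H4 pair sum is computed from
the full outer sum with the diagonal masked, exact and O(k²).

Sample overlap enters the shared-causal factor exactly: the joint BF
at a SNP is the ratio of bivariate-normal densities of (z₁, z₂) under
covariance [[1+W₁/V₁, c], [c, 1+W₂/V₂]] versus [[1, c], [c, 1]],
which factorises into the two univariate ABFs at c = 0.  H1/H2/H4 use
univariate ABFs — overlap matters most where the same SNP carries
both signals, and the exact closed form is available there; treating
the distinct-causal terms as independent is a documented
approximation.  Regions with PP(H3) ≥ 0.9 or PP(H4) ≥ 0.9 are
flagged, and the genome scan reports regions sorted by
max(PP(H3), PP(H4)).

## Cross-phenotype statistics and replication

S_hom = (wᵀR⁻¹z)²/(wᵀR⁻¹w) with w = √n and R the study correlation
matrix; under the null it is χ²₁, and with R = I and w = 1/se it
equals the squared Z of the fixed-effects IVW meta-analysis — an
identity kept as a test anchor.  S_het computes the same statistic
over the subset of studies with |z| > τ for each τ in
{0, 0.5, …, 3.0} (zero when the subset is empty) and takes the
maximum.  Its null distribution is obtained by Monte Carlo from
N(0, R) with the add-one estimator, rather than the original gamma
approximation whose constants are not recoverable from the published
description; Monte Carlo is exact up to sampling error and directly
testable.  For genome-wide scans the null sample is drawn once and
shared across variants (the null does not depend on the variant),
which bounds the attainable p at 1/(n_mc+1).

The correlation matrix R is estimated pairwise from independent null
SNPs as described above, with a nearest-positive-definite repair
(eigenvalue floor 10⁻⁶, diagonal restored) applied and logged when
sampling noise or degenerate inputs leave it non-PD.

IVW meta-analysis pools β with weights 1/se²; missing studies are
skipped and marked '?' in the METAL-style direction string.  The sign
test counts variants whose non-missing directions agree across all k
studies against the null concordance probability (1/2)^(k−1), with an
exact binomial two-sided p computed by doubling the smaller tail
(capped at 1); variants with any missing direction are excluded.

## Pipeline and reproducibility

The pipeline executes harmonise → genetic correlation →
overlap/permutation → colocalisation → CPASSOC → candidate selection
→ replication meta in dependency order, writing plain TSV/JSON
reports — the data of record — plus a manifest (input hashes,
parameters, seed, stage timings).  Per-stage random seeds are derived
from the top-level seed by fixed spawn keys, so disabling one stage
never changes another's output, and two runs with the same config and
seed produce byte-identical reports (the manifest and log, which
carry timings and timestamps, are run records rather than reports).
The QQ export pairs sorted observed and expected −log₁₀ p and
computes the genomic inflation factor λ as the median observed χ²
over the χ²₁ median (≈ 0.4549).

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale, chosen so the
Monte-Carlo bands are tight enough to detect real defects: LDSC
recovery over 50 simulated GWAS pairs at m = 20,000; permutation-null
calibration over 500 replicates of 5,000 pruned SNPs with 2,000
permutations; colocalisation recovery over 100–200 regions per
hypothesis; 10,000-variant checks for the exact identities and null
calibrations.  The original consortium analyses (≈ 75,000 pruned
SNPs, 10⁶ permutations, 1,703 blocks) are configuration, not code
changes.

## Known limitations

* Single-causal-variant colocalisation: allelic heterogeneity within
  a region dilutes all hypothesis posteriors.
* The overlap correction treats c as one scalar for all SNPs; MAF- or
  region-dependent overlap effects are not modelled.
* LD scores assume the reference LD is exact (see above).
* Fixed-effects meta-analysis only; between-cohort heterogeneity is
  surfaced through S_het and the direction strings, not through a
  random-effects model.
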