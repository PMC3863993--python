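# Methods

## The model

famscan analyzes a quantitative trait measured on members of extended
pedigrees. The trait vector is modeled as multivariate normal,

    y = X beta + g * d + a + q + e

    a ~ MVN(0, 2 Phi sigma2_a)     polygenic background
    q ~ MVN(0, Pi   sigma2_q)      locus-specific (linkage) component
    e ~ MVN(0, I    sigma2_e)      residual

where `Phi` is the kinship matrix computed recursively from the pedigree,
`Pi` is the locus-specific proportion of alleles shared identical by
descent, `d` is the minor-allele dosage of a candidate SNP and `X` holds
the intercept and any covariates. Narrow-sense heritability is
`h2 = sigma2_a / (sigma2_a + sigma2_e)` in the polygenic model.

All fits are maximum likelihood, not REML. Every test in the package is a
likelihood-ratio comparison, and several of them change the fixed-effect
design between null and alternative (the measured-genotype and joint
tests); ML keeps those log-likelihoods comparable, which REML would not.
This matches the convention of the established pedigree variance-component
tools.

## Hypothesis tests and boundary nulls

Variances are optimized on their natural scale with an explicit lower
bound of zero, so a null value on the boundary of the parameter space is
attainable exactly. The null distributions follow Self & Liang-type
mixture results:

| test                | constraint under H0          | null distribution        |
|---------------------|------------------------------|--------------------------|
| heritability        | sigma2_a = 0 (boundary)      | 1/2 chi2_0 + 1/2 chi2_1  |
| measured genotype   | gamma = 0 (interior)         | chi2_1                   |
| linkage             | sigma2_q = 0 (boundary)      | 1/2 chi2_0 + 1/2 chi2_1  |
| joint linkage/assoc | gamma = 0 and sigma2_q = 0   | 1/2 chi2_1 + 1/2 chi2_2  |

The LRT is clamped at zero when the constrained model spuriously exceeds
the full model within optimizer tolerance, and every boundary test returns
p = 1 at T = 0. LOD scores are T / (2 ln 10).

## Numerical strategy

Families are independent, so likelihoods, GLS accumulations and MVN draws
are all evaluated family block by family block; a ~630-individual
evaluation costs forty small Cholesky factorizations rather than one large
one. The general engine (`fit_ml`) optimizes the variances with L-BFGS-B
using the analytic gradient of the beta-profiled log-likelihood
(d(-lnL)/dv_k = (tr(Omega^-1 S_k) - r' Omega^-1 S_k Omega^-1 r)/2, valid
at the profiled beta by the envelope theorem). Fits are restarted from
perturbed initializations; the first restart always probes the
no-genetic-variance corner, which on small pedigrees is a frequent second
mode of the profiled surface. Default relative-lnL convergence tolerance
is 1e-8; non-convergent fits are returned flagged rather than raised.

Two-component (polygenic + residual) models — the whole MGA scan path —
use a fast rotated form instead: the eigendecomposition of 2*Phi is done
once per cohort, after which the covariance is diagonal in the rotated
basis, `sigma2 * (h lam_i + 1 - h)`, and each per-SNP fit is a weighted
regression plus a bounded one-dimensional search over the heritability
ratio h with the total variance profiled in closed form. The h = 0
endpoint is always evaluated explicitly so null fits are exact. The
rotated and general engines agree to ~1e-4 log-units (tested), and the
rotation leaves the likelihood invariant, so mixed comparisons (rotated
null vs general-path saturated model in the JLA test) are legitimate.

Three-component JLA fits cannot be pre-rotated (2*Phi and Pi do not
commute) and always use the general engine; the SNP-free, linkage-free
null is fitted once per trait on the rotated path and shared across loci.

## Genotype QC and dosages

The SNP screen mirrors family-study practice: Mendelian checking by
transmission-range logic per trio (a child allele count is impossible iff
outside [min_f + min_m, max_f + max_m] of per-parent transmissible
counts), with the *child* call blanked at flagged sites — the
minimal-data-loss reading of per-genotype blanking; a call-rate filter
(strictly below 0.95 removed); and a two-sided exact Hardy-Weinberg test
(sum of probabilities of heterozygote configurations no more probable than
the observed one, conditional on the minor-allele count) screened at 5%
FDR by Benjamini-Hochberg. HWE is computed on founders by default to
avoid relatedness-driven distortion; both the reference set and the FDR
level are arguments.

Dosages are oriented to the minor allele (ties at 0.5 break toward ALT for
determinism). Missing calls are replaced by their conditional expected
minor-allele count given all typed members of the same family — exact
single-locus peeling (sum-product elimination over the pedigree's Bayesian
network) with Hardy-Weinberg founder priors at the estimated frequency.
Multipoint imputation from flanking markers is deliberately out of scope;
the single-locus conditional expectation preserves the "weighted
covariate" contract and is exactly unbiased given the observed relatives.
An untyped individual with no typed relatives receives the population
expectation 2p.

## Trait preparation

The GWAS screen uses a pre-adjusted trait: OLS residuals on the chosen
covariates, mapped to normal quantiles by rank. The inverse-normal
transform uses the Blom offset, rank r of n -> Phi^-1((r - 3/8)/(n + 1/4)),
with ties sharing their average rank; the offset is a parameter. The JLA
path can instead estimate covariates simultaneously inside the mixed
model; the mode used is recorded in scan metadata. The MDRD eGFR utility
implements the standard 4-variable form
186 * SCr^-1.154 * age^-0.203 * 0.742^female * 1.210^black.

## Empirical thresholds

Genome-wide thresholds are calibrated by simulating null heritable traits
(polygenic + residual only) on the cohort's kinship structure, running the
full MGA scan on the real dosage panel each time, and recording all
p-values. The *significant* threshold is the lower 5% quantile of the
per-scan minimum p-value; the *suggestive* threshold is the largest p
whose expected count of null hits is at most one per scan (the
n_scans-th smallest pooled p-value). On independent uniform p-values
these converge to the Sidak forms 1 - 0.95^(1/M) and 1/M respectively
(tested). Null traits are drawn directly as MVN(0, h2 * 2Phi + (1-h2) I)
rather than by gene dropping — the covariance is identical and the draw is
one vector of standard normals in the rotated basis. Bootstrap-over-scans
percentile CIs quantify estimator precision; with fewer than 1000 scans a
warning is issued.

The genomic-control factor is lambda_GC = median(chi2_1 quantile of p) /
0.4549. The package also ships a deliberately naive OLS scan (no kinship
component) as the contrast demonstrating the inflation the mixed model
removes. For candidate-region alpha levels the effective number of tests
uses the Li-Ji eigenvalue estimator of the dosage correlation matrix with
a tolerance-guarded floor; the estimator is a documented choice and is
known to be conservative (close to the nominal count) for moderately
correlated pairs.

## The simulator and what it does (not) emulate

The generator emulates a family study of ~630 phenotyped individuals: 40
three-generation families founded by one couple each, spouses marrying in
from an unrelated population (no inbreeding, so kinship closed forms are
exact), Poisson(2.85) offspring per couple — expected family size
2 + 2m + m^2 ≈ 15.8 — ages ~ Normal(47.9, 14.8^2) truncated at 16, sexes
Bernoulli(0.5). Family-size dispersion is a free parameter of the design;
the Poisson choice is a convenience, not an estimate of any real cohort's
sibship distribution.

Genotypes are gene-dropped: founder alleles are drawn at the specified
minor-allele frequency with unique haplotype labels, children inherit one
uniformly chosen allele per parent, and locus-specific IBD is computed
*exactly* from the labels (maximum matching of label pairs; diagonal
1 + f). Gene-dropped genotypes are Mendelianly consistent by
construction. Loci are unlinked (no recombination map); a genotype
degrader adds uniform missingness and uniform genotype flips to exercise
QC. Default trait settings place h2 at 0.39 after covariates, common
target SNPs at MAF 0.36 explaining ~5% of residual variance, and rare
linked variants at MAF 0.05 with a locus-specific variance component.

What passing tests on this simulator do *not* show: robustness to
genotyping-error structure beyond uniform flips, to ascertainment through
probands, to linkage disequilibrium between scan markers (available only
through the explicit LD constructions used in the effective-tests code),
to non-normal trait distributions beyond what the rank transform absorbs,
or to pedigree loops/inbreeding (handled by the peeling engine but not
generated).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline at the
design scale (~620 individuals, 40 families) with replicate counts chosen
to keep Monte-Carlo error well inside the asserted tolerances: 100
replicates for heritability and effect-size recovery, 1000 for the
boundary-null rejection rate, 2000 null SNP tests for MGA calibration, 500
replicates for the JLA mixture null, 10,000 SNP tests for the inflation
diagnostic, and 500 scans x 1000 tests for the threshold estimator; the
acceptance script uses somewhat smaller replicate counts and records the
size next to every number it reports.

## Known limitations

* X-linked kinship, dominance variance, household/shared-environment
  components and multivariate traits are not modeled.
* The exact HWE test and the peeling imputer assume biallelic loci.
* Half-founders (one recorded parent) are rejected rather than patched.
* The JLA null mixture is asymptotic; at a few dozen small families the
  finite-sample LRT can be mildly conservative (the shipped calibration
  check quantifies this at the default design).
* Li-Ji effective-test counts for a pair of SNPs do not drop below 2 until
  the correlation is essentially 1; users wanting more aggressive
  correction can supply their own M_eff to the alpha computation.
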