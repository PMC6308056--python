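# Methods

## Statistical model

All tests assume additive allelic effects on the log-odds scale, with the
imputed dosage x ∈ [0, 2] (posterior expected allele count) standing in for
the genotype. The bi-allelic model is

    log Odds_k = β₀ + β₁ x_k + β₂ Age_k + β₃ Gender_k [+ Σ γ_j c_{j,k}]

where c_j are dosages of conditioned-on variants. Estimation is maximum
likelihood by Newton iteration (IRLS) with step halving; convergence is
declared when the largest score component falls below 1e-8 or the relative
log-likelihood change falls below 1e-10, capped at 50 iterations.
Coefficients diverging past |β| = 15 without convergence are the signature
of perfect separation and flag the result instead of reporting a p-value.
Standard errors come from the inverse observed information at the optimum
(equal to the expected information for the canonical logit link). The CI
z-quantile is fixed at 1.959964. Each test is complete-case: rows missing
the dosage or any covariate are dropped for that test only.

A multi-allelic amino-acid position with m ≥ 3 residues is tested jointly:
the full model carries the dosages of m−1 residues, the null model drops
them, and D = −2 ln(L₀/L₁) is referred to χ² with m−1 df. The reference
residue is the most frequent one — the choice does not change the LRT
(member dosages sum to 2, so any m−1 of them span the same column space),
but dropping the common residue keeps the design best conditioned. Members
that still leave the design rank-deficient (e.g. a residue perfectly
tracking a conditioned-on variant) are dropped with the df reduced and the
action logged; a position with no testable member raises an error.

Positions with exactly two residues are bi-allelic and are tested once as a
presence/absence dosage, not as a group. Residues of multi-allelic
positions are additionally tested one at a time (Present vs Absent), since
single-residue effects are what conditioning and reporting operate on.

### Multiple testing

The scan's Bonferroni threshold is α = 0.05/M with M = (number of
bi-allelic markers tested) + (number of omnibus groups, one each). The
convention for whether a multi-allelic position counts once or per residue
is not standardized; counting the group once on top of its residue markers
is the conservative reading and is what `scan` reports as `m_tests`.

### Stepwise conditional selection

Forward selection over bi-allelic terms: each step runs a full conditioned
scan, selects the smallest p below the threshold (ties broken by larger
chi-square, then lexical marker id), and adds that dosage as a covariate.
Omnibus results are computed and reported each step but are not entered as
multi-term covariate blocks: selected signals are single dosage terms,
which is what downstream conditioning, the cumulative analysis and the
joint model consume. Candidates whose fit is flagged (no variance,
collinear with selections, non-converged) are skipped for that step.
In tight LD, the step may select a perfect proxy of the causal variant
(r² = 1 residues on the same classical allele are statistically
indistinguishable); recovery is therefore assessed up to r² > 0.95 proxies.

### Permutation test

Only the status vector is permuted; dosages stay attached to their
covariate rows, so the null preserves the covariate structure while
breaking the variant-status link. The statistic is the Wald chi-square of
the variant term and perm p = (r+1)/(n_perm+1). Permutation is
unrestricted (not stratified by matching variables); with age and gender
unrelated to status under the simulated null this is exchangeable. The
default n_perm = 10,000 gives a p floor of 1e-4.

### Cumulative effect

A sample carries a locus when its dosage ≥ 0.5 (expected at least one
copy after rounding toward carriage), so K selected variants give
categories 0..K — per-locus carriage, not a 0..2K allele count, matching
how cumulative protective-variant tables are conventionally presented.
Per-category ORs versus the zero-carrier reference are crude 2×2 ratios
with Woolf CIs (Haldane–Anscombe +0.5 on zero cells) — published tables of
this form match the unadjusted computation; adjusted versions can be
obtained by fitting the category indicator in the logistic engine. The
trend test is the standard Cochran–Armitage statistic with integer scores
0..K and no continuity correction; its square equals the logistic score
test on the grouped data.

### LD and haplotypes

Dosages are hard-called at 0.5/1.5 before LD/haplotype work (the classical
tools for these analyses consume hard genotypes); calls within 0.1 of a
boundary are set missing rather than forced. Haplotype frequencies come
from the textbook EM over phase configurations: E-step weights each
individual's compatible haplotype pairs by products of current
frequencies, M-step re-counts; the log-likelihood ascends monotonically and
frequencies below 1e-6 are pruned at convergence. Initialization is the
linkage-equilibrium product of observed allele frequencies; the run is
deterministic with no restarts, so for L ≥ 3 loci a local optimum is
possible (a warning is logged). D′ and r² use the two-locus EM
frequencies with the standard sign-dependent D_max bound. Haplotype
association uses per-individual expected copies from the EM posteriors:
a per-copy ("trend") OR and a carrier OR (expected copies ≥ 0.5), both
age/gender-adjusted.

### Variance explained

Two routes, because published liability-scale figures for case-control
data do not come from a single recipe:

1. Observed-scale R² of the fitted genetic score (variant terms only,
   covariates excluded) against the 0/1 outcome, transformed by
   h²_liab = h²_obs · [K(1−K)/z²] · [K(1−K)/(P(1−P))] with z the normal
   density at the liability threshold for prevalence K and P the sample
   case fraction (the standard ascertainment-corrected transform). Note
   the transform factor *increases* with K on (0, 0.5): z shrinks roughly
   like K·t(K), so K²/z² ≈ 1/t² grows as K rises.
2. A direct liability-threshold computation from per-variant
   (frequency, OR): HWE genotype frequencies, genotype risks satisfying
   odds_g = odds₀·OR^g with odds₀ solved by root finding so the marginal
   prevalence is K, genotype thresholds inverted, and the variance of the
   genotype mean-liabilities summed across variants under linkage
   equilibrium. Solving on the odds scale (rather than treating OR as a
   risk ratio) matters once K is not small; the two coincide for rare
   disease.

Default prevalence K = 0.000078 (a five-year prevalence appropriate for a
rare carcinoma in an endemic region); configurable.

## Quality control

INFO = Var_obs(dosage) / (2 p̂ (1−p̂)) with p̂ = mean(d)/2 and the
population (divide-by-n) variance — the n vs n−1 choice shifts INFO by
O(1/n), so the convention is fixed and documented. Constant dosages give
INFO = 0 exactly; hard calls in exact HWE proportions give exactly 1.
Post-imputation defaults: drop INFO < 0.5 or MAF < 0.01 (dosage-based MAF).
Genotype QC (call rate ≥ 95%, MAF ≥ 3%, exact HWE in controls at
p ≥ 1e-6) is provided for hard-call input; sample-level QC (relatedness,
ancestry outliers) is out of scope — the pipeline consumes post-sample-QC
data.

## Synthetic cohorts

The generator emulates the object the pipeline consumes: an imputed HLA
dosage panel with known truth.

- **Haplotype structure.** Four loci (A, B, C, DRB1), four classical
  4-digit alleles each, with per-locus frequencies chosen so the planted
  effect-allele frequencies (~0.40, 0.18, 0.38, 0.19 in the population)
  bracket the control-cohort frequencies typical of protective HLA signals
  in south-Chinese case-control data. A deterministic dictionary maps each
  classical allele to residues at 6–7 amino-acid positions (at least one
  position per locus with ≥ 3 residues) and to tag-SNP alleles, so
  residue/SNP/classical dosages are exact functions of the two phased
  alleles and multi-allelic member dosages sum to 2 pre-noise. One
  multi-locus haplotype (frequency 0.03) couples the four protective
  alleles across loci; the remaining mass is at linkage equilibrium, so
  per-locus marginals are exact and the four planted signals stay nearly
  independent (pairwise r² < 0.01). Forty background SNPs in linkage
  equilibrium pad the scan.
- **Disease model.** Status ~ Bernoulli(expit(β₀ + Σ β·count + β_age·Age +
  β_gender·Gender)) on true allele counts. Default plantings: per-copy ORs
  0.57 (A Gln-62), 0.52 (rs2894207 G), 0.64 (DRB1 Phe-67), 0.64
  (B Glu-45); β_age = β_gender = 0 (no published covariate effect sizes
  exist to emulate, and frequency matching of cases and controls is
  represented by giving both strata the same covariate distributions).
- **Ascertainment.** Rejection sampling to quotas (default 1583/972) with
  intercept 0, giving a marginal case rate ≈ 0.23 — a workable rate at
  desk scale rather than the true prevalence; odds ratios are invariant to
  outcome-dependent sampling, which is precisely the property the pipeline
  relies on.
- **Covariates.** Age ~ N(46, 12) truncated at 18; gender ~ Bernoulli(0.5).
- **Imputation noise.** dosage = λ·truth + (1−λ)·2f + 0.2(1−λ)·ε with
  ε ~ N(0,1), clipped to [0, 2]; λ is tuned per variant by bisection
  against the realized INFO recomputed by the QC module. Shrinking toward
  the mean keeps allele frequencies unbiased up to clipping effects;
  target 1 returns the panel unchanged.

What the generator does **not** emulate: realistic Pan-Asian haplotype
frequencies, reference-panel-specific imputation error correlation
(errors here are independent across variants given λ), genotyping error,
population stratification, or relatedness. Passing tests therefore
demonstrate the statistical machinery is correct under the stated model,
not that any particular real cohort would yield the same variants.

## Numerical choices and degenerate inputs

- Zero-variance dosages, designs made rank-deficient by conditioning, and
  separated fits are flagged, never silently fitted.
- Tie-breaks in stepwise selection: larger chi-square, then lexical id.
- EM tolerance 1e-8 on the log-likelihood, 1000-iteration cap, pruning at
  1e-6; two-locus EM agrees with brute-force simplex maximization to 1e-3.
- Dosage files reject values outside [0, 2] by more than 1e-6 and clip the
  rest; missing values are the literal token `NA`.
- The pipeline writes every table with a header recording package version,
  seed and config hash; identical config + seed reproduce outputs
  byte-for-byte.

## Problem sizes used in validation

The test suite and the acceptance script measure properties at the study's
cohort size (2555 samples, ~150 markers) but with replicate counts chosen
for a desk-scale run: 2000 null replicates for omnibus calibration at
n = 800, 50 cohorts for stepwise recovery, 100–200 replicates for CI
coverage and bias, 200 seeds × 199 permutations for permutation
uniformity. These sizes give binomial/KS resolution comfortably finer than
the tolerances being asserted.

## Known limitations

- Stepwise selection is forward-only; no backward elimination or model
  averaging, and no credible-set posterior fine-mapping.
- No Firth penalization: very rare variants near separation are flagged
  rather than stabilized.
- Permutation is unstratified; if covariates were strongly associated with
  status, a stratified permutation would be preferable.
- EM without restarts can hit local optima for L ≥ 3 multi-allelic loci.
- The two variance-explained routes answer slightly different questions
  and will not agree exactly; neither is an unbiased estimator of GREML-
  style array heritability.
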