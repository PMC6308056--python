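# hlafinemap

Fine-mapping of the HLA region in case-control cohorts from imputed allele
dosages. The package targets the standard post-SNP2HLA analysis situation:
a dosage panel of bi-allelic SNPs, amino-acid polymorphisms and 2-/4-digit
classical HLA alleles (all in strong, structured LD), a binary disease
phenotype, and the question *which variants drive the association signal
independently?* It was built around a nasopharyngeal-carcinoma-scale study
design (≈1583 cases / 972 controls, protective HLA effects with odds ratios
0.5–0.65), but every stage is generic.

It is intended for statistical geneticists who have imputed HLA dosages
(Beagle/SNP2HLA dialect) and want a tested, scriptable implementation of the
full fine-mapping workflow — plus a synthetic-data generator with known
truth so each stage can be validated end to end.

## What it computes

- **Post-imputation QC** — imputation INFO = Var(dosage) / 2f(1−f)
  (observed dosage variance over the Hardy–Weinberg expectation) and
  dosage MAF; default filter INFO ≥ 0.5, MAF ≥ 0.01. Pre-imputation
  genotype QC (call rate, MAF, exact HWE test in controls) is included.
- **Bi-allelic association** — additive logistic regression of status on
  dosage, adjusted for age and gender (and any conditioned-on variants):
  log(Odds_k) = β₀ + β₁·x_k + β₂·Age_k + β₃·Gender_k, Wald OR with 95% CI.
- **Multi-allelic omnibus test** — for an amino-acid position with m ≥ 3
  residues, the likelihood-ratio statistic D = −2 ln(L₀/L₁) comparing the
  covariate-only model with the model carrying m−1 residue dosages;
  D ~ χ² with m−1 df.
- **Stepwise conditional selection** — repeat the scan conditioning on all
  previously selected variants; stop when no variant passes the Bonferroni
  threshold 0.05/M.
- **Permutation confirmation** — case-control labels permuted against
  intact (dosage, covariate) rows; perm p = (r+1)/(n_perm+1).
- **Cumulative effect** — per-sample count of carried protective loci
  (dosage ≥ 0.5), crude per-category ORs vs the zero-carrier reference
  (Woolf CI), and the Cochran–Armitage trend test.
- **LD and haplotypes** — pairwise D′/r² from hard calls, EM haplotype
  frequencies over multi-allelic classical loci, and per-haplotype
  carrier/trend association from EM phase posteriors.
- **Variance explained** — observed-scale R² of the fitted genetic score,
  transformed to the liability scale at a stated prevalence K
  (h²_liab = h²_obs · [K(1−K)/z²] · [K(1−K)/(P(1−P))]), plus a direct
  liability-threshold computation from per-variant (frequency, OR) pairs.

The synthetic-data module generates cohorts from classical-allele
haplotypes with a deterministic allele→residue/SNP dictionary, planted
logistic effects, quota-based case-control ascertainment and imputation
noise calibrated to a target INFO — so parameter recovery is checkable
against known truth.

## Worked example

```python
from hlafinemap import RunConfig, run

summary = run(RunConfig(seed=41, n_perm=50), "example_out")
print(summary["selected"])
for row in summary["joint_model"]:
    print(row["marker_id"], round(row["or"], 2), f'{row["p"]:.2e}')
print(round(100 * summary["h2"]["h2_liability"], 2), "%")
```

With seed 41 this simulates the default cohort (1583 cases / 972 controls,
four planted protective effects, one per locus), runs QC, the scan, and
stepwise selection, and prints:

```
['AA_C_116_31344853_F', 'AA_A_156_30018778_Q', 'AA_DRB1_11_32654558_S', 'AA_B_116_31429976_L']
AA_C_116_31344853_F 0.5 2.74e-16
AA_A_156_30018778_Q 0.61 3.95e-15
AA_DRB1_11_32654558_S 0.63 2.18e-12
AA_B_116_31429976_L 0.69 3.22e-06
2.35 %
```

Each selected marker is a perfect LD proxy (r² = 1) of one planted variant:
residues carried by the same classical allele are indistinguishable from
the causal one — exactly the ambiguity HLA fine-mapping faces — and the
joint-model odds ratios recover the planted 0.57/0.52/0.64/0.64 within
sampling error. The last line is the liability-scale variance explained by
the four selected terms at prevalence 0.000078.

The same pipeline runs from the shell:

```bash
hlafinemap run-all --seed 41 --out example_out
hlafinemap simulate --seed 7 --out sim_out     # dosage/sample/pheno files
```

## Layout

```
src/hlafinemap/
  dosage_io.py      # SNP2HLA-dialect parsing, panels, alignment, grouping
  synthetic_data.py # truth-known cohort generator + imputation noise
  qc.py             # INFO score, dosage and genotype QC
  association.py    # logistic engine, Wald tests, omnibus LRT, scans
  conditional.py    # stepwise selection, permutation test
  cumulative.py     # carrier counts, category ORs, Cochran-Armitage
  ld_haplo.py       # D'/r2, EM haplotypes, haplotype association
  heritability.py   # observed/liability-scale variance explained
  pipeline.py, cli.py
docs/methods.md     # models, assumptions, parameter choices, limitations
```
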