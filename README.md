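# chemohf

Genetic association toolkit for **chemotherapy-related heart failure
(CRHF)** — heart failure attributable to anthracycline and/or trastuzumab
exposure.  The package is for statistical geneticists and cardio-oncology
researchers who want to test whether a variant (or a gene's genetically
imputed expression) is a *specific* risk factor for CRHF rather than a
marker of chemotherapy exposure or of heart failure in general.

## What it implements

**Composite-null frequency test.**  With CRHF cases and two control groups
— patients treated with the same chemotherapy without heart failure, and
heart-failure patients never exposed to it — each group's variant count is
an independent binomial.  The null is the union

&nbsp;&nbsp;&nbsp;&nbsp;H₀: p_case = p_ctrlA  **or**  p_case = p_ctrlB,

tested by a likelihood-ratio statistic T = 2(ℓ̂ − ℓ̂₀), where ℓ̂₀ ties the
case proportion to whichever control gives the larger profile likelihood
(pooled MLE, other control free).  T is calibrated by parametric bootstrap
under the constrained null MLEs; two one-sided bootstrap tests are
combined by the min-P rule (two-sided p = twice the smaller one-sided p,
capped at 1).  An exact enumeration oracle verifies the bootstrap on small
problems.

**TWAS stage.**  Elastic-net expression weights trained on a reference
panel of paired genotypes and expression, dosage-weighted expression
imputation into a cohort, and OLS association of imputed expression with
ΔLVEF (decline in left-ventricular ejection fraction) adjusted for age,
baseline LVEF, antihypertensive use and two genotype principal components.

**Per-variant association.**  Additive-model (0/1/2 dosage) logistic
regression with covariates, crude allele-count odds ratios with Woolf
intervals, and the covariate-adjusted linear ΔLVEF model.

**Synthetic cohorts.**  No individual-level data from the motivating
cohorts are public, so a generator produces cohorts with the study's
structure (group sizes 38/282/690, Hardy–Weinberg genotypes at the
published per-group frequencies, covariates, additive ΔLVEF phenotype) and
reference panels where expression is a sparse linear function of local
dosages.  Published summary tables are embedded as fixtures and every
reproducible printed number is recomputed as a self-check.

See `docs/methods.md` for the model details and design decisions.

## Worked example

Test one variant given per-group counts (carriers out of samples, or
alleles out of 2·samples with `level="allele"`):

```python
from chemohf import CompositeNullTest, ThreeGroupCounts

counts = ThreeGroupCounts(
    k_case=4, n_case=76,        # 4 of 76 case alleles
    k_ctrl_a=7, n_ctrl_a=564,   # chemo, no HF
    k_ctrl_b=21, n_ctrl_b=1380, # HF, no chemo
    level="allele",
)
result = CompositeNullTest(counts, variant_id="rs57242572").fit(
    B=100_000, seed=1
)
print(result.summary())
```

```
Composite-null variant-frequency test (allele level, parametric-bootstrap)
================================================================
variant:        rs57242572
counts:         case 4/76, ctrlA 7/564, ctrlB 21/1380
frequencies:    case 0.0526, ctrlA 0.0124, ctrlB 0.0152
null ties case to control B at 0.0172
LRT:            3.9936
one-sided p:    high 0.01542, low 1
two-sided p:    0.03084   (min-P: twice the smaller one-sided p)
replicates:     B = 100000, seed = 1
```

Reading the output: the case allele frequency (0.053) exceeds both
controls; the best-fitting null ties the case to the nearer control (B) at
the pooled frequency 0.017; the high-side bootstrap tail gives a one-sided
p of 0.016, doubled to a two-sided p ≈ 0.031 — the variant is more
frequent in CRHF cases than in *both* control groups.

The same test from a VCF and sample table, and the rest of the pipeline,
are available from the CLI:

```bash
chemohf simulate --seed 7 --out cohort/
chemohf test-composite --vcf cohort/cohort.vcf --samples cohort/samples.tsv \
    --snp rs57242572 --level carrier --B 100000 --seed 7
chemohf assoc --vcf cohort/cohort.vcf --samples cohort/samples.tsv \
    --case-group hf_no_chemo --control-group chemo_no_hf --covar sex,antihtn
chemohf run --config configs/demo.yaml --seed 7 --out demo_run
```

`chemohf run` executes simulate → QC → composite tests → logistic scan →
TWAS → report, writing TSV tables and a `manifest.json` that makes the run
byte-for-byte reproducible.

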