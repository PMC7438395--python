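# Methods

## Scientific setting

Chemotherapy-related heart failure (CRHF) is heart failure attributable to
anthracycline and/or trastuzumab exposure.  A variant that is a *specific*
risk factor for CRHF should have a case frequency different from both of
two contrast groups: patients who received the same cardiotoxic therapy
without developing heart failure ("chemo, no HF"), and patients with heart
failure never exposed to that therapy ("HF, no chemo").  A difference from
only one group is explained by either chemotherapy tolerance or generic
heart-failure risk, not by their interaction.  `chemohf` implements the
statistical machinery for this three-group design together with its two
companions — a transcriptome-wide association stage (TWAS) on imputed
expression and per-variant additive logistic/linear models — and a
synthetic-cohort generator, because no individual-level data from the
motivating cohorts are public.

## The composite-null frequency test

Let k_c/n_c, k_A/n_A, k_B/n_B be event counts (carriers of a variant out of
samples, or alternate alleles out of 2·samples) in cases and the two
control groups, each modelled as an independent binomial with success
probability p_c, p_A, p_B.  The null hypothesis is the *union*

    H0:  p_c = p_A  or  p_c = p_B,

an intersection-union-type composite null.  The test statistic is the LRT

    T = 2 [ sup_{p} ℓ(p) − sup_{p ∈ H0} ℓ(p) ],

where the unconstrained supremum is at the per-group MLEs k/n and the
constrained supremum is the better of two scenarios: tie the case to
control A at the pooled MLE (k_c+k_A)/(n_c+n_A) with p_B free, or the
symmetric scenario with control B.  The scenario comparison is exact (both
profile likelihoods have closed forms); ties break deterministically toward
control A and are recorded.  T is clipped at zero against floating-point
negatives.

Because only a group factor enters the model, this binomial formulation is
likelihood-equivalent to a saturated logistic regression of case membership
with two contrast parameters; covariates inside this test are deliberately
unsupported.

### Calibration

T has no usable asymptotic reference distribution at the null boundary
(the constraint set is a union, and the interesting variants are rare), so
the null distribution is estimated by **parametric bootstrap**: B triples
are redrawn from binomials at the constrained null MLEs and each replicate
is refitted exactly like the observed data.  Case resampling cannot be used
here — the null must be *imposed*, and only the fitted constrained model
imposes it.

Two one-sided tests are combined by the min-P rule.  The one-sided
statistics are T⁺ = T·1[f̂_c > p̃] and T⁻ = T·1[f̂_c < p̃], where p̃ is the
tied-control pooled null frequency of the same dataset; a zero LRT falls in
neither tail.  One-sided p-values use the add-one estimator
(#{T* ≥ T_obs}+1)/(B+1) (never zero), and the two-sided p-value is
min(1, 2·min(p⁺, p⁻)).  When the observed one-sided statistic is zero its
p-value is 1 by construction, so the doubling is driven by the occupied
tail.

An **exact enumeration oracle** computes the same p-values by summing
binomial pmf products over the full outcome space; it is restricted to
spaces of at most 10⁶ outcomes and exists to verify the bootstrap (the
test suite checks agreement within 3 Monte-Carlo standard errors on random
tiny instances) and to anchor correctness on hand-checkable cases.

Operating characteristics, recomputed by the test suite and the acceptance
script: at a boundary null (case frequency exactly equal to one control's)
at the study group sizes 38/282/690, the empirical size at nominal 0.05
over 2,000 simulated datasets stays within Monte-Carlo noise of nominal;
off the boundary the union null makes the test conservative, and power is
monotone in the case-frequency displacement.

### Event level

The published outcome is *presence* of a variant, so the default event
level is carrier counts; allele-level counts (out of 2n) are a flag and
are used when reconstructing the published table, whose frequency columns
are labelled as minor-allele frequencies.  Which level produced the
published p-values is not documented; both are supported and the level is
recorded in every result.

### Count reconstruction from printed frequencies

Published per-group frequencies are printed to three decimals; the fixture
builder inverts them to integer counts by rounding freq × denominator.
Where no integer count rounds back to the printed value (true of a few
published cells, e.g. 0.013 with 282 samples at allele level — plausibly a
missing-data denominator in the source) a warning is attached and the
check is marked unattainable rather than forced.

## TWAS stage

Weight training is elastic-net regression (mixing parameter 0.5, the
conventional choice for expression prediction; penalty strength by 5-fold
cross-validation) of measured expression on standardized dosages in a
reference panel, via scikit-learn.  The cross-validated R² at the selected
penalty is reported; models with cv_r2 ≤ 0 or no nonzero weights are
flagged unusable and excluded, not errors.  Standardization statistics
(per-variant mean and scale) travel with the weight model so imputation is
reproducible in any cohort: the imputed score is Σ w_j (d_j − μ_j)/σ_j.
Model variants absent from a cohort contribute zero with a logged missing
weight-mass fraction; above 50% missing mass imputation refuses.

Association is OLS of ΔLVEF (lowest follow-up minus baseline left
ventricular ejection fraction, percentage points) on the score, adjusted
for age, baseline LVEF, antihypertensive use, and the first two genotype
principal components (mean-imputed, column-centered SVD; component signs
fixed so the largest-magnitude loading is positive).  Genes are ranked by
raw p-value — the reference analysis reports ranks, not adjusted
p-values — with optional Benjamini–Hochberg q-values labelled as an
extension.  A rank-deficient design raises an error naming the collinear
columns rather than silently dropping one.

## Per-variant association

The general heart-failure comparison is additive-model logistic regression
(dosage 0/1/2) with sex and antihypertensive-use indicators, fitted by
statsmodels' maximum likelihood.  Separation, non-convergence and
monomorphic variants yield flagged results with diagnostics — the rare
variant with zero control carriers is exactly the published "NA" case.
Crude allele-count odds ratios use the Haldane–Anscombe 0.5 correction for
zero cells and Woolf intervals; with a binary predictor and no covariates
the logistic estimate equals the closed-form 2×2 log-OR (asserted to
1e-6).  The ΔLVEF linear model mirrors the TWAS covariate set.
Per-variant p-values are reported unadjusted, matching the source
presentation; a Bonferroni column over the 16-SNP panel is optional.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis assumes:
three groups of 38/282/690 samples, Hardy–Weinberg genotypes at the
published per-group allele frequencies, per-group covariate distributions
(sex ratio and age from the published demographics; antihypertensive-use
probabilities 0.5/0.3/0.6 chosen to be higher in the heart-failure groups),
baseline LVEF ~ Normal(62, 5), and ΔLVEF = intercept + Σ effect·dosage +
Normal(0, σ) with default intercept −4, σ = 7 LVEF points and a −3
point/allele effect on one signal SNP so the demo pipeline has something
to find.  The reference panel draws allele frequencies uniformly on
[0.05, 0.5] and generates expression as a sparse linear function of
dosages plus Gaussian noise (159 samples by default, matching the size of
the expression training set the reference analysis used).

Deliberately *not* emulated: linkage disequilibrium (loci are
independent), population stratification, genotyping error and
missingness-by-platform (missing rate defaults to 0, matching the
reported 100% duplicate concordance), and covariate–genotype confounding
(covariates are group-dependent but genotype-independent; making the
per-group covariate models differ is the confounding hook).  Passing tests
therefore demonstrate correctness of the estimators and calibration of the
test under the assumed model, not robustness to LD or stratification in
real data.

## Determinism and numerics

One master seed; per-stage child seeds by fixed offsets, so stages can be
rerun independently and a manifest (config snapshot + seed + output
digests) reproduces every table byte-for-byte.  Likelihoods use the
0·log 0 = 0 convention so boundary MLEs are exact; the LRT is clipped at
zero; bootstrap p-values are add-one smoothed; scenario ties break toward
control A.  Percentages print to one decimal, frequencies to three,
p-values to three with a "<0.001" floor.

## Problem sizes in the validation suites

The operating-characteristic checks use sizes chosen to make Monte-Carlo
noise small relative to the asserted margins while keeping the suites
quick: 2,000 datasets × B = 1,000 for boundary size; 20 tiny instances ×
B = 20,000 against the exact oracle; 100 end-to-end TWAS replicates with
50 genes (6 SNPs each, panels of 300, cohorts of 400); B = 10⁶ for the
reconstructed published-table p-values.

## Known limitations

* The published composite-test p-values are approximate targets only: the
  event level (carrier vs allele) and the exact one-sided statistic of the
  original analysis are undocumented, and a few printed frequencies are
  not exactly invertible to counts.  The implementation reproduces the
  published qualitative pattern (which variants are small-p) and matches
  the two clearest signals to within rounding (0.03 vs published
  0.031/0.030).
* The composite test supports exactly two control groups and no
  covariates.
* TWAS weight training assumes a complete reference panel; no
  cross-tissue model libraries or fine-mapping.
* Firth-penalised logistic regression is out of scope; separation is
  flagged, not rescued.
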