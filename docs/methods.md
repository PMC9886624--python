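# Methods

## The score

The genetic risk score is a fixed six-variant weighted allele count,
`GRS_i = Σ_j X_ij β_j`, with per-allele weights on the serum 25(OH)D₃
Z-score scale taken from a large vitamin D GWAS (packaged in
`src/vdgrs/data/weights_6snp.tsv`). Two weights are negative (*SEC23A*
rs8018720, *GC* rs2282679); the score may equivalently be computed with
positive weights on the non-effect allele (`flip_negative_weights`), which
adds the constant `2·Σ|β_neg| = 0.212` to every complete-genotype raw score
and leaves the Z-scored score bit-identical — the package tests this
equivalence to 1e-12.

Z-scoring (of both the score and the phenotype) is done within the cohort
being analysed, with the sample (n−1) SD. Strata of a cohort reuse the
cohort-wide Z-scores; no per-stratum re-standardization is performed, so
stratified slopes remain comparable to the pooled one.

## Allele bookkeeping

* **Harmonization.** A weight's effect/other alleles are matched against the
  genotype file's REF/ALT directly, then after reverse-complementing the
  weight alleles (strand flip). Effect-on-ALT keeps the stored ALT dosage;
  effect-on-REF maps it through `2 − x`. Palindromic variants (A/T, C/G)
  make the flip undetectable from labels, so they are refused unless the
  rsid is explicitly whitelisted. The packaged pipeline defaults whitelist
  rs8018720: the panel includes it, its genotyping here is assay-based
  (strand known), and without the whitelist the panel could never be scored
  in full. That judgement — that the assay strand matches the weight
  table's — is ours and is the main caveat of the whitelist default.
* **Proxies.** A panel SNP absent from the data may be replaced by a
  declared high-LD proxy with an explicit two-allele bijection (target
  allele → proxy allele); the beta is untouched and the matrix column is
  re-keyed back to the canonical rsid, so downstream code never sees proxy
  ids. The packaged table declares rs6538691 as proxy for rs10745742 with
  the T alleles corresponding (and, the alleles of the proxy being otherwise
  undocumented, assumes the C alleles correspond too). LD itself is never
  computed — proxy r² is carried as information only.
* **Dosage TSV input** has no REF/ALT, so values are taken as effect-allele
  dosages already in the weight table's orientation.

## QC thresholds

Variants fail on folded MAF < 0.01, HWE p < 1e-5, call rate < 90%, or
imputation info < 0.3 (skipped when absent); samples fail on > 10% missing
panel variants. The HWE test is the 1-df chi-square goodness of fit of
observed genotype counts against p²/2pq/q² at the sample allele frequency —
the conventional choice at biobank scale, and exactly checkable (counts
50/0/50 give statistic 100). Fractional (imputed) dosages bypass HWE, which
needs hard calls; the report records this as a missing `hwe_p`. Both QC
passes are idempotent: filtering an already-filtered matrix removes nothing.

Missing dosages at scoring time follow a selectable policy: `mean_impute`
(default — substitute 2×effect-allele frequency of the non-missing samples,
matching common scoring tools), `skip_variant`, or `drop_sample`. Which of
these the original analyses used is not documented anywhere we know of; the
default is our choice and the other two are one flag away. A sample missing
every variant is flagged absent rather than scored.

## Association stage

All models are OLS with intercept on complete cases (exclusion counts
logged), two-sided t-test p-values, via statsmodels. The predictor screen
fits `vd_z ~ candidate + age + sex` per candidate (dose enters as
`log(1+dose)`), and applies Benjamini–Hochberg across the candidate
p-values at FDR 0.05. The multivariable model is
`vd_z ~ grs_z + age + sex + bmi + supplementing + ms_status`, fitted pooled
and within supplementation strata (the stratum drops the constant
supplementing term; ms_status is retained where it varies). Model fit is
summarized by adjusted R² — the `(n−1)/(n−p−1)` correction — for the
covariate-only and +GRS models. Genotype-distribution differences between
cases and controls use a Pearson chi-square on the 2×3 table (zero-count
genotype columns collapsed, reducing df).

## The synthetic generator

Genotypes are independent Binomial(2, p_j) draws (HWE, linkage
equilibrium); the six real loci are genome-scattered, so independence is a
mild idealization, but it ignores any residual LD and all ancestry
structure. Default effect-allele frequencies are plausible European-range
values fixed once (0.40, 0.75, 0.40, 0.79, 0.82, 0.72 in panel order); no
frequencies are published for the source cohorts.

The phenotype is generated on the Z-score scale and mapped to nmol/L as
`50 + 20·Z` for file output only (arbitrary, documented here). The genetic
component enters as `grs_effect · g_std`, where `g_std` standardizes the
weighted allele count by its analytic HWE moments (mean `Σ2pβ`, variance
`Σ2p(1−p)β²`). This makes `grs_effect` *equal* the standardized per-SD
genetic effect the association stage estimates — the quantity published for
the validation cohort (0.14 SD in non-supplementers, 0.17 in supplementers)
— instead of leaving it an opaque function of the residual SD.

Modes:

* **additive** — `vd = grs_effect·g_std + supp_shift·S +
  dose_effect·log(1+dose)·S + covariates + ε`. Genetics acts equally in both
  strata.
* **titration** — non-supplementers as above (no dose term); supplementers
  dose toward a target: `vd = titration_target +
  attenuation·grs_effect·g_std + covariates + ε`. Covariate terms are kept
  in both strata so they share covariate structure; the dose effect is
  absorbed by the target. Attenuation 0 removes the genetic signal from
  supplementers by construction.

Supplementation is Bernoulli per MS status (defaults 0.711 / 0.267); doses
are log-normal with group medians 1200 / 571 IU/day (`median = exp(μ)`,
`σ_log = 0.5` — doses are positive and right-skewed, and only medians are
published). BMI ~ N(27, 4.5²), age ~ N(55, 8²) (both lightly clipped), sex
Bernoulli(0.745 female) in the study preset.

### Calibration of the study preset

The titration-mode defaults are calibrated in closed form (reproduced by
`scripts/calibrate.py`): with supplementer fraction w_s ≈ 0.523, the
variance budget on the pre-Z scale is

| component | value |
|---|---|
| between strata, `target²·w_s·w_n` | 0.336 |
| covariates (BMI −0.035/kg·m⁻², age +0.010/yr, female +0.05) | 0.032 |
| genetic, `w_n · grs_effect²` with grs_effect = 0.205 | 0.020 |
| residual, `0.78²` | 0.608 |

Total ≈ 1, base-model R² ≈ 0.37, pooled GRS coefficient ≈ `w_n·0.205` ≈
0.098. Note that a pooled coefficient of ~0.1 on a standardized,
covariate-orthogonal regressor yields an incremental adjusted R² of
≈ 0.1² ≈ 0.01, so the model with the score sits at ≈ 0.38: the published
pair (0.37 → 0.39 alongside a 0.1-SD coefficient) cannot be matched in both
quantities simultaneously, and this package reports the coefficient-
consistent value. MS status has no direct phenotype effect; its marginal
association arises entirely through the higher supplementation prevalence
and dose in MS, which is the mechanism the analysis itself argues for.

The biobank preset (additive, supplementation 5.1%, no dose effect since
doses are unrecorded there) sets per-stratum residual SDs to
`sqrt(1 − grs_effect² − Var_covariates)` so each stratum has unit phenotype
variance and the within-stratum standardized slope equals the configured
effect in expectation. Desk runs default to n = 50,000 rather than the
full ~354k; estimates are unbiased and the SE at 50k (≈0.004) is already
far below the effects of interest.

### The variance-explained formula

`expected_variance_explained` returns `Σ 2p_j(1−p_j)β_j²`, the additive
genetic variance of the score on a unit-variance phenotype under HWE and
linkage equilibrium. With the packaged betas this quantity is bounded by
`0.5·Σβ² = 0.0057` for *any* frequencies; the shipped defaults give 0.0046
(0.46%). The ~2.4% figure quoted in the vitamin D literature for panels
like this one derives from the source GWAS's own variance accounting and is
not reproducible from these per-allele Z-score weights via this formula —
the package computes and reports the formula's honest value rather than
rescaling weights or frequencies to force agreement.

### What passing tests do and do not show

The generator reproduces the *statistical skeleton* the analysis assumes:
HWE genotypes, stratum-specific supplementation behaviour, a phenotype
whose variance decomposition mirrors the published model fits. It does not
emulate ancestry structure or relatedness, seasonality (reported
non-significant in the design this mirrors), latitude/geography,
measurement error of dried-blood-spot assays, or dose misreporting.
Parameter-recovery tests therefore validate the estimation machinery, not
the epidemiology of any real cohort.

## Numerical and design choices

* Seeds: every stochastic routine takes a numpy `Generator` or integer
  seed; fixed seeds give bit-identical outputs (tested).
* Problem sizes in the test suite and acceptance script: 200 study-scale
  replicates (n = 547) and single biobank-scale draws (n = 50,000 /
  18,882), chosen so Monte-Carlo error is an order of magnitude below the
  tolerances being checked.
* Z-scoring of a constant vector, scoring with zero variance, empty strata,
  all-zero chi-square tables and rank-deficient designs all raise typed
  errors (or skip with a warning, for strata) rather than returning NaN.
* Multi-allelic and non-SNP VCF records are skipped with a warning; rsid
  matching is by ID field, never position.
* BH rather than any other FDR procedure: the screened family is tiny and
  independent-ish; BH is the field default when only "FDR < 5%" is stated.

## Known limitations

Six SNPs cannot support ancestry inference, relatedness checks or LD
operations, and none are attempted — ancestry enters only as an optional
exclusion label upstream of this package. The score is a fixed panel;
there is no p-value thresholding, clumping, or multi-score support. The
titration and additive modes bracket, but cannot distinguish, the
behavioural explanations for a supplementer-stratum null: that question
needs dose-response data the design does not collect.
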