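# Methods

## Phenotypes

The 14-item heroin-use and craving questionnaire scores each item 0–4.
Part I (items 1–6) is summed to the *urge* subscore (0–24), Part II
(items 7–14) to the *ability-to-overcome* subscore (0–32); their sum is
the *total* craving score (0–56). Higher is more severe. All three are
analysed as quantitative traits. Records with any missing item are not
imputed; they are excluded from phenotype analysis and the exclusion
count is logged (`HUCScorer.n_unscorable_`).

## Genotype QC

- **Allele frequencies / call rate** per SNP from non-missing calls;
  calls are unordered allele pairs normalized alphabetically.
- **HWE**: the plain 1-df chi-square goodness-of-fit statistic
  `sum((O-E)^2/E)` with expected counts `(n p^2, 2npq, n q^2)` at the
  estimated allele frequency. No continuity correction and no exact
  test: the statistic is the classical goodness-of-fit form, adequate at
  the sample sizes (hundreds) and MAFs (> 0.05) this pipeline targets.
  Monomorphic SNPs are flagged, not errors, because simulated cohorts
  can produce them.
- **Duplicate concordance** over designated sample pairs: matching
  pair-calls / jointly non-missing pair-calls, per SNP and overall.
- **Filter defaults**: maf > 0.05 (the conventional panel-selection
  threshold for this design), HWE alpha = 1e-4, call rate >= 0.9. The
  latter two are conventional defaults, configurable; a threshold of 0
  disables its check.

## Association model

For SNP coded `g` and phenotype `y` (complete cases only):

- unadjusted: `y = b0 + b1 g + e`
- adjusted:   `y = b0 + b1 g + b2 age + b3 sex + b4 bmi + e`
  (sex coded 0 = female, 1 = male, everywhere in the package)

Codings are relative to a designated *risk allele*: additive = copies
(0/1/2), dominant = carrier (0/1), recessive = homozygote (0/1). The
reported p-value is the genotype coefficient's two-sided t-test p in
each fit — not the omnibus F — and the reported R² is the unadjusted
genotype-only model R², i.e. marginal variance explained. Both fits use
the same joint complete-case subject set so their p-values are
comparable. OLS is delegated to statsmodels; the test suite verifies it
against an independent normal-equations oracle to 1e-8.

Descriptive cohort tests: Pearson chi-square contingency tests without
continuity correction, and pooled-variance two-sample t tests (Welch
optional), callable from raw vectors or from (n, mean, sd) summaries.

No multiple-testing correction is applied by default, matching the
candidate-gene practice this pipeline reproduces (a few dozen SNPs,
raw p < 0.05); Bonferroni and Benjamini-Hochberg corrections are
available as flags and their use is logged.

## Risk coding and the GRS

Per-SNP codings are either **additive** (risk allele = the allele whose
homozygote has the higher stratified phenotype mean; codes = copies) or
**binary** — one homozygote class versus the rest. For the binary
family, the homozygote split with the larger absolute (n-weighted) mean
separation is selected and the higher-mean side becomes the risk (= 1)
group; the recorded mode is "recessive" when the risk group is the lone
homozygote and "dominant" when it is the carrier pair. These two labels
are orientation duals of the same grouping, which is why the
`mode_policy` values "recessive", "dominant" and "binary" all select
this family. `best_fit` additionally fits the additive candidate and
keeps the smallest genotype-coefficient p (ties: larger R², then
additive first). Exactly tied means raise and require an explicit
coding.

The GRS is the unweighted sum of per-SNP codes. The bundled five-variant
reference model (GRIN3B rs2240158 C-carrier = 1; GRIN3A rs3983721
TT = 1; CYP2C19 rs6583954 additive in T; TPH2 rs2129575 TT = 1; COMT
rs174699 CC = 1) spans 0–6. Missing component genotypes exclude a
subject from the score by default (`missing_policy="exclude"`), because
unweighted sums over partially observed panels are not comparable across
subjects; `"partial"` sums observed components and flags the subject.

**Circularity.** Learning risk directions from the cohort being scored
biases the subsequent trend test optimistic. The estimator emits a
standing warning whenever it learns in-sample and accepts a frozen
`RiskModel` (TSV-serializable) for honest evaluation; the pipeline's
run log repeats the warning.

**Trend test.** The phenotype is regressed on the integer GRS as a
continuous covariate (unadjusted by default; covariate-adjusted variant
available); "p for trend" is the GRS coefficient's p. An ordinal
(per-level) treatment would also be defensible; continuous was chosen as
the standard dose-response test and the per-level means ladder is
reported alongside for inspection.

## Synthetic cohorts

The generator draws what the linear model assumes:

- **Genotypes**: per SNP, HWE trinomial `(p^2, 2pq, q^2)` at the
  configured MAF; SNPs are independent (no LD, no stratification — the
  analysis treats SNPs marginally, so the test bed does too).
- **Covariates**: sex Bernoulli(prop_male = 259/326 ≈ 0.79); age and BMI
  normal within sex (male 43.2 ± 7.2 y, 23.0 ± 2.8 kg/m²; female
  37.8 ± 6.3 y, 21.6 ± 2.8 kg/m²), floored at plausibility bounds
  (age ≥ 18, BMI ≥ 14).
- **Latent phenotype**: `intercept + sum(beta_j * centered code_j) +
  covariate effects (centered) + N(0, residual_sd)`. Centering makes
  `intercept` the population mean (default 27.3, the scale of the
  cohort's observed mean total). Covariate effects default to 0,
  consistent with the near-null sex differences in craving scores this
  design reports.
- **Items**: the latent value is clipped to [0, 56], rounded, and dealt
  over the 14 items round-robin (1 point at a time, capped at 4), which
  preserves the total exactly — the total being the analysed quantity.
  Consequence: the urge/ability split of a simulated total is close to
  the 6/14 : 8/14 item ratio, slightly different from the real cohort's
  subscale means; subscale-specific effect sizes are therefore
  approximate in simulation while total-score behaviour is exact.
- **Default panel**: the five reference SNPs with each effect sized (via
  `effect_size_for_r2`) to explain ~4% of a total SD of 9.9, i.e. the
  3–5% per-variant scale typical of this design; residual SD is reduced
  so the total SD stays ~9.9. The five MAFs (0.20–0.35) are plausible
  values for the study population, chosen once — they are not printed in
  any source and only shape power, not correctness.
- **Ascertainment**: optional upper-tail truncation at a configured
  quantile of the total score, emulating recruitment from the extreme
  margin of the phenotype range (severe addicts in MMT). Refitting after
  truncation attenuates effect estimates, as range restriction should;
  a test asserts the direction.
- **Missingness**: independent per-call blanking at a configured rate.
- **Reproducibility**: one global seed, split into four substreams
  (genotypes, covariates, noise, missingness) so changing one
  component's parameters does not perturb the others. Identical
  (config, seed) gives identical cohorts; the pipeline's outputs are
  byte-stable.

What passing simulation tests does *not* show: robustness to LD between
panel SNPs, population stratification, non-Gaussian residuals,
informative missingness, or questionnaire measurement error — none of
which the generator produces.

The simulator defaults to n = 326 subjects. (Published descriptions of
this cohort give both 326 and 316; the larger, table-consistent figure
is used and the discrepancy left unresolved.)

## Numerical and design choices

- Rank-deficient designs and zero-variance responses are hard errors
  naming the offending column; degenerate two-sample t tests (zero
  pooled variance) return p = 1 when means agree and error otherwise.
- Association results render at 6 significant digits; all report files
  are plain TSV and deterministic (no timestamps).
- Validation-scale choices in the test suite: type-I calibration uses
  1000 null replicates at n = 326; R²-recovery 200 replicates at
  n = 2000; combined-vs-single 200 replicates at n = 326; HWE
  calibration 2000 replicates at n = 1000 — sizes at which the binomial
  99% acceptance bands are informative while the suite stays fast.

## Known limitations

- The GRS is unweighted by design; no effect-size weighting, shrinkage,
  LD-aware methods or cross-validation (deliberately out of scope).
- The in-sample risk-direction learning reproduces a common but
  optimistic practice; use frozen models for unbiased inference.
- VCF support is read-only (GT field, biallelic records); no PLINK or
  dosage formats.
- All SNPs are treated as autosomal; no X-chromosome dosage handling.
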