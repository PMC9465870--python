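# Methods

## The causal question and the estimators

The package estimates effects of habitual sleep duration (hours per 24 h)
on pregnancy and perinatal outcomes using genetic variants as instrumental
variables. A valid instrument must associate with the exposure, share no
cause with the outcome, and affect the outcome only through the exposure.
Under those assumptions the Wald ratio β_zy/β_zx of a variant's outcome and
exposure associations estimates the causal effect per 1 h/day; with many
variants the IVW estimate pools the ratios with weights β_zx²/se_zy²,
algebraically a weighted regression of β_zy on β_zx through the origin.

Sensitivity estimators relax the no-pleiotropy assumption in different
directions: MR-Egger frees the intercept (its intercept estimates average
directional pleiotropy; exposure associations are oriented non-negative
first, otherwise the intercept is meaningless); the weighted median is
consistent while variants carrying ≥50 % of the weight are valid. Between-
variant heterogeneity is summarized by Cochran's Q (χ², k−1 df), and
leave-one-out re-estimation screens for single influential variants.

Binary outcomes are analysed throughout on the log-odds scale and
presented as odds ratios; birthweight in grams. Inference is normal-theory
(summary statistics come from large samples), except after Rubin's-rules
pooling, where the conventional small-sample t reference with
df = (m−1)(1 + W/((1+1/m)B))² is used.

### Split cross-over design

When the exposure GWAS was conducted in the analysis cohort itself,
two-sample MR with those weights would re-use the same individuals. The
split cross-over design randomly halves the cohort, estimates per-SNP
exposure and outcome associations in each half, crosses them (exposure A ×
outcome B, and vice versa), and combines the two MR estimates by
fixed-effects inverse-variance meta-analysis. The halves are disjoint, so
each crossed estimate is a genuine two-sample estimate; the cost is
weak-instrument attenuation toward the null, since each half's instrument
associations carry twice the sampling noise. With k instruments jointly
explaining a fraction R² of exposure variance in a half-sample of size
n/2, the expected multiplicative attenuation of IVW is approximately
R²/(R² + 2k/(n·E[2pq])) — about 0.82 at n = 100 000 for the default panel.
This is a property of the design itself, not of the implementation, and it
is why the parameter-recovery study below estimates its IVW arm from
full-cohort summary statistics.

### Nonlinear MR by residual stratification

Stratifying directly on the exposure would condition on a collider
(exposure is a descendant of both the instrument and the confounders) and
bias within-stratum IV estimates. Instead the exposure is regressed on the
GRS (optionally with covariates), and each woman's *residual* duration —
observed duration minus her mean-centred genetic contribution — defines
the strata. The residual is independent of the score by construction, so
within-stratum Wald ratios (GRS→outcome slope over GRS→duration slope,
logistic or linear as appropriate) are unbiased local effects. Differences
across strata are tested two ways: Cochran's Q of the stratum estimates,
and weighted meta-regression of the estimates on the stratum mean of
observed duration (under a quadratic dose–response with curvature b the
meta-regression slope approaches the derivative's slope 2b). The same two
tests applied to the per-stratum GRS→duration slopes form the IV-constancy
diagnostic.

**Granularity limitation.** Reported duration is an integer. The genetic
contribution of the default panel has SD ≈ 0.1 h — far below the 1-hour
reporting granularity — so the residual clusters tightly around integer
values and residual strata nearly coincide with raw-duration strata.
Quantile cuts that land inside an integer cluster select individuals *by
their genetic score*, which distorts (inflates or deflates) within-stratum
GRS→duration slopes; in degenerate cases a stratum's slope is ~0 and its
IV estimate is reported with an enormous SE (and therefore ignored by the
downstream weighted tests). This is a property of the method with
coarsely reported exposures, not a bug: the IV-constancy diagnostic exists
precisely to flag it, and it fires reliably on integer-reported synthetic
data. Consequently the package's *methodological* guarantees (collider-bias
removal, per-stratum unbiasedness) are stated — and verified in the test
suite — on the continuous exposure scale, while the pipeline's default
analysis of reported hours mirrors field practice and carries the
diagnostic.

### Pattern classification

The qualitative label for a stratum profile (U-shaped, reverse-J, J,
linear-positive/negative, null, inconclusive) is produced by an ordered
rule table over CI-based signs of the lowest stratum, highest stratum,
middle strata, and the overall linear MR estimate ("+" = 95 % CI above the
null, "−" = below, "0" = spanning). The table is data
(`DEFAULT_PATTERN_RULES`), not code, and callers may supply their own.
Because the label demands CI exclusion at both extremes, it is a
deliberately conservative read-out: profiles whose extreme strata are
individually non-significant are labelled inconclusive even when the
meta-regression detects curvature decisively.

### Observational arm

Duration categories (≤5, 6–7, 8–9, ≥10 h/day, reference 8–9) enter either
as indicators or recoded to midpoints 3.5/6.5/8.5/11 h (the open-ended
categories use the plausible 1–23 h reporting range). The midpoint model
is nested in the categorical model; 2·ΔLL with df = (categories−1)−1 = 2
tests nonlinearity. Per-imputation fits are pooled by Rubin's rules
(T = W + (1+1/m)B); the chained-equations imputation engine itself is out
of scope — the module pools fits produced by any imputer, and the tests
feed it fits from MCAR-completed synthetic stacks.

## The synthetic-cohort generator

The generator reproduces the statistical structure the analysis assumes,
not any real cohort:

* **Panel**: 78 independent biallelic SNPs (no LD), allele frequencies
  uniform on (0.05, 0.95), Hardy–Weinberg dosages. Per-SNP effects have
  equal magnitude and random sign — only the aggregate variance explained
  is identified from published sources — and are rescaled so the genetic
  component explains `target_r2` (default 0.69 %) of exposure variance.
  Equal magnitudes make the unweighted allele count (the GRS actually used)
  carry the same R² as the weighted genetic value. At 175 499 women this
  yields F ≈ 1200 for the score.
* **Exposure**: baseline 7.2 h + genetic component + 0.3 h per SD of a
  single standard-Gaussian composite confounder + N(0, 1.1²) noise
  (total SD ≈ 1.15 h, range ≈ 2–12 h, matching self-reported duration in
  large cohorts). Reported hours are rounded to the nearest integer and
  clipped to [1, 23]; rounding attenuates the reported-hours R² by ~5 %,
  well inside the calibration tolerance. Implausible values (<2 or >12 h)
  are *retained* by the generator and removed only by `exposure_qc`,
  mirroring the study pipeline's order of operations.
* **Outcomes**: binary outcomes are Bernoulli(expit(α + f(x) + γ·U)) with
  the intercept α solved by bisection (tolerance 1e-4 relative) so the
  marginal prevalence hits the requested value; f is null, linear,
  quadratic, or continuous piecewise-linear, always anchored to f = 0 at
  its reference duration (default 8 h). Birthweight is Gaussian
  (mean 3500 g, residual SD 450 g). Prevalence is configuration, not a
  constant, because it varies sharply across real cohorts.
* **Fetal genotypes**: one allele Bernoulli(maternal dosage/2) plus one
  population allele — mother–child dosage correlation 0.5, giving the
  expected halving of fetal-path effects in unadjusted maternal models.
* **Missingness**: MCAR uniform, or MAR logistic in a fully observed
  driver (unit slope per driver SD, intercept solved for the marginal
  rate).

What the generator does **not** emulate: LD between instruments, strand
ambiguity beyond allele labels, assortative mating, selection into the
cohort, heavy-tailed or digit-preference reporting, per-confounder
structure (a single composite stands in for the seven-confounder block),
or survival outcomes. Passing tests therefore demonstrate correctness of
the estimators and the design's statistical properties under the assumed
structure — not robustness to those real-data features.

## Numerical choices

* Per-SNP association scans use batched closed-form OLS (shared-covariate
  Frisch–Waugh partialling) and batched Newton–Raphson logistic fits; with
  dosage regressors and no covariates the logistic fit collapses to
  per-genotype-class sufficient statistics. Agreement with statsmodels is
  to ~1e-8 and is enforced by tests.
* Logistic non-convergence (separation) yields a flagged record with
  missing SE, never an exception; binary outcomes with zero cases raise,
  naming the outcome. Strata with no cases yield missing estimates plus a
  warning and are dropped from Q/meta-regression.
* Quantile stratification is stable rank-and-cut (mergesort order, cuts at
  ⌊i·n/k⌋), so group sizes are equal up to ties and reproducible.
* Harmonization flips outcome alleles/sign/frequency to the exposure
  orientation; incompatible allele sets are excluded with a logged reason.
  Palindromic (A/T, C/G) variants are dropped when MAF > 0.42 (default),
  configurable to keep/drop-all; the threshold is the common community
  convention, since same-strand coding cannot be assumed in general.
* IVW defaults to multiplicative random effects (SE × √max(1, Q/(k−1)));
  fixed effects by flag. Wald SEs are first-order delta by default,
  second-order by flag. Weighted-median SE uses a seeded 1000-draw
  parametric bootstrap; its point estimate uses the midpoint cumulative-
  weight convention with linear interpolation.
* All simulation entry points take explicit seeds (numpy `SeedSequence`
  spawning); identical configuration + seed gives byte-identical report
  files.

## Study sizes used by the verification suite

The replicate studies in `tests/test_acceptance.py` run at sizes chosen to
keep Monte-Carlo error well below each assertion's tolerance on a single
CPU: null calibration at 1000 replicates of n = 20 000; linear-effect
recovery at 350 cohorts of n = 100 000 (three outcome draws each) for the
stratum arm and 90 cohorts × two draws for the IVW arm; nonlinearity
detection at 50 replicates of n = 100 000; the collider-bias contrast at
500 replicates of n = 50 000. `scripts/acceptance.py` uses one cohort of
n = 175 499 for instrument-strength and single-cohort analyses plus a
40 × 50 000 recovery study.

## Known limitations

* Residual stratification with integer-reported exposure approximates
  raw stratification (see above); the doubly-ranked method, which
  addresses this, is out of scope.
* The conservative CI-based pattern rules under-call "U-shaped" at
  moderate signal; treat the label as a summary, and the meta-regression
  as the test.
* No LD clumping, proxy lookup, Steiger filtering, MR-PRESSO,
  multivariable MR, or fractional-polynomial dose–response estimation.
* One-sample IVW on full-cohort summary statistics is unbiased only when
  exposure–outcome confounding of the *outcome model* is absent or
  negligible; the pipeline's default linear-MR arm therefore uses the
  split cross-over design and documents its attenuation instead.
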