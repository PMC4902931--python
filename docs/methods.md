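# Methods

This note records the statistical model behind `urinadjust`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
test bed does and does not establish about real data.

## Dilution model and adjustment family

A spot urine sample's analyte concentration C (μg/L) is modelled as
log-linear in the urinary flow rate U (mL/min):

    ln C = a + D − b · ln U + ε,

where a is the ln concentration at the standard flow of 1 mL/min, b is the
analyte-specific dilution exponent, D is the person's latent internal dose
on the ln scale, and ε is residual noise. b = 1 would mean concentrations
scale exactly inversely with flow; empirically b is well below 1 for the
analytes handled here, which is why excretion rates (which multiply by U,
i.e. assume b = 1) overshoot and flip the sign of the UFR correlation
rather than removing it.

The implemented adjustments are per-record transforms (no cohort state
except the osmolality reference), hence they commute with subsetting and
are equivariant under unit rescaling of the concentration. Unit
conventions made explicit in code: μg/L ≡ ng/mL, so the excretion rate in
ng/hr equals 60 · C · U with U in mL/min; blood Pb in μg/dL against urine
in μg/L needs no conversion anywhere because all inference is done on ln
scale, where multiplicative unit changes shift the mean only.

## Exponent derivation

The exponent grid is {0.00, 0.01, …, 1.50}, 151 points, both endpoints
included. Because ln(C·U^b) = ln C + b ln U, the correlation at every grid
point is an explicit function of five sample moments and the whole profile
is evaluated at once. r(b) against ln U is non-decreasing in b — its
derivative has the sign of var(lnU)·var(lnC) − cov², non-negative by
Cauchy–Schwarz — so criterion A (minimise |r|) has a single sign change and
the grid optimum lies within half a step of the analytic root
−cov(lnC, lnU)/var(lnU), clipping to 0 or 1.5 when the root leaves the
grid. Conventions, stated because any choice here is arbitrary: ties break
to the smallest b; if the adjusted series is exactly constant
(perfect cancellation) its correlation is defined as 0; criterion B
maximises the *signed* correlation with ln blood, so a pathological
negative optimum is reported rather than silently flipped. Closed-form
refinement beyond the grid exists in the API but is off by default; the
0.01 grid is the documented procedure.

Derivation refuses to run on a cohort tagged as the testing split
(`SplitLeakageError`) unless explicitly overridden, and assessment refuses
exponent tables whose provenance says they were derived on the testing
split. Subgroup derivation (gender × ethnicity, or the age bands 6–11,
12–19, 20–39, 40–59, >60) skips groups under 4 records with a warning and
reports the within-group regression slope p-value so under-powered groups
are visible.

## Assessment

The cohort is partitioned 80:20 by simple random sampling (stratified
sampling is available behind a flag); the training size is
round(0.8·n) under round-half-even — at n = 2151 this gives 1721/430.
Geometric means are used throughout because the distributions are
positively skewed. Pearson correlations are computed on natural-log
transformed data; p-values come from t = r√((n−2)/(1−r²)) on n−2 df and
95% intervals from Fisher's z ± 1.96/√(n−3). Correlations of different
adjustment methods with a shared variable (UFR, or blood) are dependent,
so pairwise method comparisons use the Hotelling–Williams t on n−3 df,
taking as r23 the observed correlation between the two adjusted series.
The compact letter display is built by insert-and-absorb: start with one
letter covering all methods, split every letter containing a significantly
different pair, absorb subsets; this provably never separates a
non-significant pair nor merges a significant one (verified by brute force
in the tests). Two numerically identical adjusted series (between-series
r = 1 to machine precision, e.g. a b = 0 power adjustment versus
unadjusted) are treated as a non-significant pair rather than fed to the
test, whose statistic is undefined there. No family-wise correction is
applied beyond the pairwise α = 0.05 display. Correlations within 1e-12
of ±1 are snapped to ±1 and flagged degenerate, with a collapsed interval.

## Eligibility cascade

Thresholds are read literally: ACR strictly > 30 mg/g (mg/L albumin over
g/L creatinine is mg/g directly); glucose inclusive ≥ 126 mg/dL at ≥ 8 h
fasting, ≥ 200 mg/dL otherwise; eGFR strictly < 60 mL/min/1.73 m². The
2009 CKD-EPI equation with the black-race coefficient is used for adults —
kept deliberately as historically faithful to the three-ethnicity design
this cascade models, not as current clinical practice — and Bedside
Schwartz (0.413·height/Scr) under age 18. Whether serum creatinine was
standardized, and how missing fasting times should be handled, are not
specified by the source design; missing covariates are a config choice:
strict (error naming record and field) or drop-with-reason. The non-detect
stage removes records lacking detection for any of urinary Pb, Cd, *total*
As (not the inorganic sum) or I. Audits carry per-record reasons and
reconcile exactly: input = output + Σ removed, and filtering is idempotent.

## Synthetic cohort generator

The generator is the package's no-download test bed and encodes the study
conditions:

* **Scales.** Geometric means: UFR 0.7 mL/min, creatinine 1.1 g/L,
  osmolality 635 mOsm/kg, urinary Pb 0.5 / Cd 0.2 / As_IMM 6.3 / I 149
  μg/L, blood Pb 1.1 μg/dL, blood Cd 0.3 μg/L. Exponents b: Pb 0.38,
  Cd 0.32, As_IMM 0.27, I 0.45, creatinine 0.52. ln UFR SD 1.0.
* **Free parameters.** The survey source does not characterise the joint
  distribution of dose and hydration, so the dose and noise SDs are this
  package's choices: they were set so the unadjusted ln correlations with
  UFR land in the weak range reported for pooled spot-urine data
  (≈ −0.25 to −0.4) and the blood couplings (0.95 Pb, 0.80 Cd) so the
  best-case urine–blood correlations reach ≈ 0.8 / 0.65. The osmolality
  surrogate exponent (0.40) is likewise inferred from the published
  pattern of near-zero osmolality-adjusted UFR correlations, which
  requires an effective exponent near the analyte b values.
* **Blood coupling.** Blood concentrations load on the latent dose only,
  never on UFR, so criteria A and B are genuinely different targets. An
  optional `dose_ufr_corr` couples dose to hydration; with it positive,
  the criterion-A estimate is biased by −ρ·σ_dose/σ_U while criterion B
  stays near the generative exponent — the pooled-data pathology that
  makes criterion B the more robust choice in single-void designs.
* **Censoring.** Detection limits are placed at the configured quantile of
  each analyte's exact marginal; non-detects store the limit itself
  (never zero) with a false detect flag. Note a consequence: excluding
  non-detects left-truncates the concentration distribution, which
  attenuates the fitted exponent below the generative value (at the
  default 6% censoring, Pb comes out near 0.29 rather than 0.38). This
  selection effect is inherent to censoring-based exclusion, not an
  estimator defect; recovery tests therefore run the generator with
  censoring off.
* **Exclusion covariates** are generated marginally independent of the
  dilution variables (no joint structure is specified by the source
  design) and trigger each rule at its configured rate exactly: the
  albumin-creatinine ratio is lognormal with P(ACR > 30) equal to the
  albuminuria rate, and serum creatinine is placed on the correct side of
  the per-record eGFR = 60 boundary by closed-form inversion of the
  CKD-EPI/Schwartz equations.
* **Not emulated:** survey weights and clustering; multiple voids per
  person over hydration states; truncation of marginal ranges (only the
  correlation structure matters downstream). Passing tests on this
  generator show the estimators are correct under the stated model; they
  do not show the model captures every feature of real survey data.

Everything is drawn from one seeded generator in a fixed order: identical
parameters give a byte-identical serialized cohort.

## Problem sizes in the verification suite

The test suite and acceptance script size their simulations to the design
they verify: grid/closed-form agreement on 1,000 random instances at
n ∈ {50, 428, 1723}; exponent recovery over 200 replicate cohorts at
n = 1723 with censoring and dose spread off; sign-flip structure at
n = 10,000; Williams-test calibration over 10,000 trivariate-normal
simulations at n = 428; cascade rate calibration at n = 10,000 with 3
binomial-SE bands; the acceptance script runs the full pipeline from an
initial synthetic cohort of 3,539 records, which the default exclusion
rates carry to ≈ 2,150 eligible records and a ≈ 1,720/430 split.

## Known limitations

* Criterion-A exponents inherit the truncation attenuation described
  above whenever censoring-based exclusion precedes derivation.
* The Williams test and the Fisher-z interval are large-sample
  approximations; both are validated by simulation at the n used, not
  proved exact.
* The CKD-EPI variant implemented is the 2009 race-coefficient form;
  modern race-free equations give different eGFR values and a different
  cascade.
* Single-void data cannot identify within-person exponents; the derived b
  is a population-level quantity and is not proposed for reuse elsewhere.
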