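# urinadjust

Hydration adjustment of spot-urine biomarker concentrations, for
biomonitoring and environmental-epidemiology studies that measure analytes
(Pb, Cd, inorganic-plus-methylated arsenic, iodine, …) in single urine
voids. A spot sample's concentration depends on how dilute the urine
happens to be; this package implements the standard family of corrections,
derives the empirical flow-rate exponent that several of them need, and
scores every method against objective performance criteria.

## The model

Urinary dilution is driven by the urinary flow rate, UFR = V/t (mL/min),
where V is void volume and t the time since the previous void.
Concentrations follow an analyte-specific log-linear dilution law

```
ln C = a − b · ln UFR + noise,
```

with b (Araki's b) the analyte's dilution exponent. The adjustment methods:

| method      | formula                    | units                 |
|-------------|----------------------------|-----------------------|
| creatinine  | C / C_cr                   | μg/g creatinine       |
| osmolality  | C · Osm_ref / Osm_meas     | μg/L at Osm_ref       |
| ER          | C · V / t                  | ng/hr                 |
| ERBW        | C · V / (t · BW)           | ng/kg-hr              |
| UFR power   | C · UFR^b                  | μg/L at UFR = 1 mL/min|

ER implicitly assumes b = 1 and overcompensates when the true b < 1. The
UFR-power exponent is derived per analyte by evaluating the Pearson
correlation of the ln-adjusted concentration over a b grid (0 to 1.5, step
0.01) on a training split, either minimising |r| against ln UFR
(**criterion A**, hydration removal — its analytic optimum is the OLS slope
−cov(lnC, lnU)/var(lnU)) or maximising r against the ln blood concentration
of the same analyte (**criterion B**, internal-dose tracking). Methods are
compared on a held-out testing split; correlations sharing a variable are
compared with the Hotelling–Williams test and summarised as a compact
letter display.

Eligibility filtering reproduces the standard health-based cascade:
albuminuria (ACR > 30 mg/g), diabetes (self-report or glucose ≥ 126 mg/dL
fasting / ≥ 200 mg/dL non-fasting), chronic kidney disease (self-report or
eGFR < 60 mL/min/1.73 m², 2009 CKD-EPI for adults, Bedside Schwartz under
18), then removal of records with non-detects for urinary Pb, Cd, total As
or I.

A synthetic cohort generator (`urinadjust.synthetic`) reproduces the
statistical structure all of this assumes — log-linear dilution, a latent
internal dose shared between urine and blood, creatinine and osmolality as
imperfect UFR surrogates, demographic strata, exclusion covariates and
detection limits — so the whole pipeline runs and is testable without any
data download.

## Worked example

```python
import numpy as np
import urinadjust as ua

cohort = ua.generate_cohort(ua.default_params(n=3539, seed=7))
filtered, audits = ua.apply_exclusions(cohort)
for a in audits:
    print(f"{a.stage}: removed {a.removed}, remaining {a.remaining}")

split = ua.split_cohort(filtered, fraction=0.8, seed=7)
train, test = split.apply(filtered)
print(f"training n={train.n}, testing n={test.n}")

table_a, _ = ua.derive_b_table(train, criterion="A")
table_b, _ = ua.derive_b_table(train, criterion="B", analytes=("pb", "cd"))
print(table_a[["analyte", "b_opt", "r_opt"]].to_string(index=False))

osm_ref = float(np.median(train.data["osmolality"]))
reports, rankings = ua.evaluate_methods(test, table_a, table_b, osm_ref=osm_ref)
for rep in reports:
    if rep.analyte == "pb" and rep.criterion == "A":
        print(f"pb A {rep.method:10s} r={rep.r_p:+.3f} "
              f"({rep.ci_low:+.3f}, {rep.ci_high:+.3f}) {rep.letter_group}")
print("criterion A ranking (pb):", " > ".join(rankings[("pb", "A")]))
```

prints

```
albuminuria_diabetes_ckd: removed 890, remaining 2649
nondetect: removed 508, remaining 2141
training n=1713, testing n=428
analyte  b_opt     r_opt
     pb   0.27 -0.002341
     cd   0.28 -0.001215
 as_imm   0.24  0.003151
      i   0.40 -0.004627
pb A unadjusted r=-0.298 (-0.382, -0.209) e
pb A creatinine r=+0.193 (+0.100, +0.283) d
pb A osmolality r=+0.074 (-0.021, +0.167) c
pb A er         r=+0.538 (+0.467, +0.602) g
pb A erbw       r=+0.506 (+0.432, +0.573) f
pb A ufra       r=-0.056 (-0.150, +0.039) b
pb A ufrb       r=+0.030 (-0.065, +0.124) a
criterion A ranking (pb): ufrb > ufra > osmolality > creatinine > unadjusted > erbw > er
```

Reading this: the exclusion cascade trims the cohort in two audited stages;
the grid search finds each analyte's dilution exponent with a residual
training correlation below the grid resolution (|r_opt| < 0.005); on the
held-out split, unadjusted Pb correlates negatively with UFR (dilution),
excretion rates flip it strongly positive (overcompensation), while the
tuned UFR-power and osmolality adjustments leave little hydration signal.
Letters mark methods whose correlations are statistically
indistinguishable (Williams test, α = 0.05).

The same stages are available from a shell:

```
urinadjust generate --n 3539 --seed 7 --out cohort.csv
urinadjust filter --cohort cohort.csv --out filtered.csv
urinadjust run --out-dir run    # full pipeline with manifest
```

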