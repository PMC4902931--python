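"""Eligibility filtering: kidney-function equations and the exclusion cascade.

Records with evidence of albuminuria (albumin-creatinine ratio > 30 mg/g),
diabetes (self-report, or plasma glucose ≥ 126 mg/dL after ≥ 8 h fasting /
≥ 200 mg/dL otherwise) or chronic kidney disease (self-report, or estimated
glomerular filtration rate < 60 mL/min/1.73 m²) are removed first; records
lacking a detectable concentration for any of urinary Pb, Cd, total As or I
are removed second.  eGFR uses the 2009 CKD-EPI equation for adults and the
Bedside Schwartz equation for volunteers under 18 — the CKD-EPI variant
with the black-race coefficient is kept deliberately, as historically
faithful to the three-ethnicity design this cascade was built around,
rather than as current clinical practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "ExclusionAudit", "egfr_ckd_epi", "egfr_schwartz", "flag_albuminuria",
    "flag_diabetes", "flag_ckd", "apply_exclusions",
    "ACR_THRESHOLD", "GLUCOSE_FASTING", "GLUCOSE_NONFASTING", "EGFR_THRESHOLD",
]

ACR_THRESHOLD = 30.0        # mg albumin per g creatinine, strict >
GLUCOSE_FASTING = 126.0     # mg/dL at >= 8 h fasting, inclusive
GLUCOSE_NONFASTING = 200.0  # mg/dL at < 8 h fasting, inclusive
FASTING_CUTOFF_H = 8.0
EGFR_THRESHOLD = 60.0       # mL/min/1.73 m^2, strict <
ADULT_AGE = 18.0

#: Analytes whose non-detection excludes a record (total As, not As_IMM).
NONDETECT_GATES = ("detect_pb", "detect_cd", "detect_total_as", "detect_i")


@dataclass
class ExclusionAudit:
    """One filter stage's removal record."""

    stage: str
    removed: int
    remaining: int
    reasons: dict = field(default_factory=dict)  # sqn -> list of rule names

    def to_dict(self) -> dict:
        return {"stage": self.stage, "removed": self.removed,
                "remaining": self.remaining,
                "reasons": {str(k): v for k, v in self.reasons.items()}}


def egfr_ckd_epi(serum_creatinine, age, gender, ethnicity=None):
    """2009 CKD-EPI estimated glomerular filtration rate (mL/min/1.73 m²).

    141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age
    · 1.018 [female] · 1.159 [non-Hispanic black];
    κ = 0.7 (female) / 0.9 (male), α = −0.329 (female) / −0.411 (male).
    Intended for adults; callers with age < 18 belong with
    :func:`egfr_schwartz`.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be > 0")
    female = np.asarray(gender) == "female"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (141.0
            * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.209
            * 0.993 ** np.asarray(age, dtype=float)
            * np.where(female, 1.018, 1.0))
    if ethnicity is not None:
        egfr = egfr * np.where(np.asarray(ethnicity) == "non-Hispanic black",
                               1.159, 1.0)
    return egfr if egfr.ndim else float(egfr)


def egfr_schwartz(height, serum_creatinine):
    """Bedside Schwartz eGFR for volunteers under 18: 0.413 · height / Scr."""
    h = np.asarray(height, dtype=float)
    scr = np.asarray(serum_creatinine, dtype=float)
    if np.any(h <= 0) or np.any(scr <= 0):
        raise ValueError("height and serum creatinine must be > 0")
    out = 0.413 * h / scr
    return out if out.ndim else float(out)


def flag_albuminuria(urinary_albumin, urine_creatinine):
    """True iff albumin-creatinine ratio exceeds 30 mg/g (strict >).

    Albumin in mg/L over creatinine in g/L yields mg/g directly.
    """
    alb = np.asarray(urinary_albumin, dtype=float)
    cr = np.asarray(urine_creatinine, dtype=float)
    if np.any(cr <= 0):
        raise ValueError("urine creatinine must be > 0 (ratio undefined)")
    out = alb / cr > ACR_THRESHOLD
    return out if out.ndim else bool(out)


def flag_diabetes(selfreport, plasma_glucose=None, fasting_hours=None):
    """True iff self-reported, or glucose ≥ 126 mg/dL fasting / ≥ 200 otherwise."""
    self_rep = np.asarray(selfreport, dtype=bool)
    if plasma_glucose is None:
        out = self_rep
    else:
        gluc = np.asarray(plasma_glucose, dtype=float)
        fast = np.asarray(fasting_hours, dtype=float)
        fasting = fast >= FASTING_CUTOFF_H
        out = self_rep | np.where(fasting, gluc >= GLUCOSE_FASTING,
                                  gluc >= GLUCOSE_NONFASTING)
    return out if out.ndim else bool(out)


def flag_ckd(selfreport, egfr=None):
    """True iff self-reported CKD or eGFR < 60 mL/min/1.73 m² (strict <)."""
    self_rep = np.asarray(selfreport, dtype=bool)
    if egfr is None:
        out = self_rep
    else:
        out = self_rep | (np.asarray(egfr, dtype=float) < EGFR_THRESHOLD)
    return out if out.ndim else bool(out)


def egfr_for_record(age, gender, ethnicity, serum_creatinine, height):
    """Dispatch the eGFR equation by age (< 18 → Bedside Schwartz)."""
    age_arr = np.asarray(age, dtype=float)
    adult = egfr_ckd_epi(serum_creatinine, age_arr, gender, ethnicity)
    child = egfr_schwartz(height, serum_creatinine)
    out = np.where(age_arr < ADULT_AGE, child, adult)
    return out if out.ndim else float(out)


_STAGE1_COVARIATES = ("urinary_albumin", "urine_creatinine", "plasma_glucose",
                      "fasting_hours", "serum_creatinine", "selfreport_diabetes",
                      "selfreport_ckd")


def apply_exclusions(cohort: Cohort, strict: bool = True) -> tuple[Cohort, list[ExclusionAudit]]:
    """Run the two-stage exclusion cascade with a full audit trail.

    Stage 1 removes records flagged for albuminuria, diabetes or CKD;
    stage 2 removes records with a non-detect on any of urinary Pb, Cd,
    total As or I.  Under ``strict=True`` a missing stage-1 covariate raises;
    otherwise the record is dropped with reason ``missing:<field>``.
    """
    df = cohort.data
    n0 = len(df)
    reasons1: dict = {int(s): [] for s in df["sqn"]}

    missing_mask = pd.Series(False, index=df.index)
    for col in _STAGE1_COVARIATES:
        miss = df[col].isna()
        if miss.any():
            if strict:
                sqn = int(df.loc[miss, "sqn"].iloc[0])
                raise ValueError(f"record sqn {sqn} missing required field '{col}'")
            for s in df.loc[miss, "sqn"]:
                reasons1[int(s)].append(f"missing:{col}")
            missing_mask |= miss

    ok = ~missing_mask
    sub = df.loc[ok]
    alb = flag_albuminuria(sub["urinary_albumin"].to_numpy(float),
                           sub["urine_creatinine"].to_numpy(float))
    dia = flag_diabetes(sub["selfreport_diabetes"].to_numpy(dtype=bool),
                        sub["plasma_glucose"].to_numpy(float),
                        sub["fasting_hours"].to_numpy(float))
    egfr = egfr_for_record(sub["age"].to_numpy(float), sub["gender"].to_numpy(),
                           sub["ethnicity"].to_numpy(),
                           sub["serum_creatinine"].to_numpy(float),
                           sub["height"].to_numpy(float))
    ckd = flag_ckd(sub["selfreport_ckd"].to_numpy(dtype=bool), egfr)
    for sqn, a, d, c in zip(sub["sqn"], np.atleast_1d(alb), np.atleast_1d(dia),
                            np.atleast_1d(ckd)):
        if a:
            reasons1[int(sqn)].append("albuminuria")
        if d:
            reasons1[int(sqn)].append("diabetes")
        if c:
            reasons1[int(sqn)].append("ckd")
    reasons1 = {s: r for s, r in reasons1.items() if r}
    keep1 = ~df["sqn"].astype(int).isin(reasons1)
    df1 = df.loc[keep1].reset_index(drop=True)
    audit1 = ExclusionAudit("albuminuria_diabetes_ckd", removed=n0 - len(df1),
                            remaining=len(df1), reasons=reasons1)

    reasons2: dict = {}
    for col in NONDETECT_GATES:
        nd = ~df1[col].fillna(False).astype(bool)
        for s in df1.loc[nd, "sqn"]:
            reasons2.setdefault(int(s), []).append(f"nondetect:{col.removeprefix('detect_')}")
    keep2 = ~df1["sqn"].astype(int).isin(reasons2)
    df2 = df1.loc[keep2].reset_index(drop=True)
    audit2 = ExclusionAudit("nondetect", removed=len(df1) - len(df2),
                            remaining=len(df2), reasons=reasons2)

    audits = [audit1, audit2]
    out = Cohort(df2, audit=list(cohort.audit) + [a.to_dict() for a in audits],
                 provenance=dict(cohort.provenance))
    return out, audits
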