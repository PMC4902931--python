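"""Synthetic spot-urine cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes: each urinary analyte follows the log-linear dilution model

    ln C = a + D − b · ln UFR + ε,

where UFR is the urinary flow rate (mL/min), b is the analyte-specific
dilution exponent, D is a latent (between-person) internal dose on the
natural-log scale and ε is residual measurement/biological noise.  Blood
concentrations of the same analyte are coupled to the latent dose D (not to
UFR), so that "correlation with UFR" and "correlation with blood" are
genuinely different optimisation targets for the exponent.  Creatinine and
osmolality are generated from their own log-linear blocks and therefore act
as imperfect surrogates of UFR.  Demographics follow configurable
gender/ethnicity/age-band proportions, eligibility covariates trigger the
albuminuria / diabetes / chronic-kidney-disease exclusions at configurable
rates, and concentrations below per-analyte detection limits are flagged
non-detect (the limit itself is stored as a placeholder, never zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort, ETHNICITIES

__all__ = ["AnalyteParams", "SurrogateParams", "SyntheticParams",
           "generate_cohort", "default_params"]

_KAPPA = {"female": 0.7, "male": 0.9}
_ALPHA = {"female": -0.329, "male": -0.411}

#: Fixed split of As_IMM into species (As III, As V, MMA, DMA).
SPECIES_FRACTIONS = {"as3": 0.14, "as5": 0.06, "mma": 0.18, "dma": 0.62}
#: Share of total urinary As that is As_IMM (remainder: arsenobetaine etc.).
AS_IMM_SHARE_OF_TOTAL = 0.8


@dataclass(frozen=True)
class AnalyteParams:
    """Generative block for one urinary analyte.

    ``gm`` is the target geometric mean (μg/L) at the cohort's UFR
    distribution; the ln-scale intercept ``a`` (concentration at
    UFR = 1 mL/min) is derived from it unless given explicitly.
    ``dose_ufr_corr`` correlates the latent dose with ln UFR; the default 0
    keeps dose and hydration independent (the pooled-data attenuation
    mechanism is obtained by setting it nonzero).
    """

    gm: float
    b_true: float
    sigma_dose: float
    sigma_noise: float
    blood_coupling: float = 0.0
    blood_gm: float | None = None
    blood_sigma: float = 0.0
    nondetect_rate: float = 0.0
    lod: float | None = None
    dose_ufr_corr: float = 0.0
    a: float | None = None


@dataclass(frozen=True)
class SurrogateParams:
    """Log-linear block for a dilution surrogate (creatinine or osmolality)."""

    gm: float
    b_true: float
    sigma: float
    a: float | None = None


@dataclass(frozen=True)
class SyntheticParams:
    n: int = 2151
    seed: int = 0
    ufr_mu: float = math.log(0.7)
    ufr_sigma: float = 1.0
    analytes: dict[str, AnalyteParams] = field(default_factory=lambda: {
        # gm / b from large-survey training-data values; noise scales chosen
        # so unadjusted ln-correlations with UFR and with blood land in the
        # weak-to-moderate range typical of pooled spot-urine data.
        "pb": AnalyteParams(gm=0.5, b_true=0.38, sigma_dose=0.90,
                            sigma_noise=0.60, blood_coupling=0.95,
                            blood_gm=1.1, blood_sigma=0.70,
                            nondetect_rate=0.06),
        "cd": AnalyteParams(gm=0.2, b_true=0.32, sigma_dose=1.00,
                            sigma_noise=0.72, blood_coupling=0.80,
                            blood_gm=0.3, blood_sigma=0.60,
                            nondetect_rate=0.06),
        "as_imm": AnalyteParams(gm=6.3, b_true=0.27, sigma_dose=0.55,
                                sigma_noise=0.40, nondetect_rate=0.05),
        "i": AnalyteParams(gm=149.0, b_true=0.45, sigma_dose=0.85,
                           sigma_noise=0.62, nondetect_rate=0.04),
    })
    creatinine: SurrogateParams = field(
        default_factory=lambda: SurrogateParams(gm=1.1, b_true=0.52, sigma=0.55))
    osmolality: SurrogateParams = field(
        default_factory=lambda: SurrogateParams(gm=635.0, b_true=0.40, sigma=0.30))
    gender_proportions: dict[str, float] = field(default_factory=lambda: {
        "male": 0.51, "female": 0.49})
    ethnicity_proportions: dict[str, float] = field(default_factory=lambda: {
        "non-Hispanic white": 0.49, "non-Hispanic black": 0.28,
        "Mexican American": 0.23})
    #: (lo_age, hi_age, proportion) per band.
    age_bands: tuple = ((6, 11, 0.08), (12, 19, 0.16), (20, 39, 0.32),
                       (40, 59, 0.27), (60, 80, 0.17))
    #: (mean, sd) of height (cm) and bodyweight (kg) per age band.
    height_by_band: tuple = ((140, 12), (163, 10), (170, 10), (169, 10), (166, 10))
    weight_by_band: tuple = ((38, 10), (62, 14), (80, 18), (83, 18), (78, 15))
    exclusion_rates: dict[str, float] = field(default_factory=lambda: {
        "albuminuria": 0.10, "diabetes": 0.09, "ckd": 0.08})

    def validate(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 2):
            raise ValueError("n must be an integer >= 2")
        if not (np.isfinite(self.ufr_mu) and np.isfinite(self.ufr_sigma)
                and self.ufr_sigma >= 0):
            raise ValueError("ufr_mu/ufr_sigma must be finite with sigma >= 0")
        for name, blk in self.analytes.items():
            for attr in ("gm", "b_true", "sigma_dose", "sigma_noise",
                         "blood_coupling", "nondetect_rate", "dose_ufr_corr"):
                v = getattr(blk, attr)
                if not np.isfinite(v):
                    raise ValueError(f"analyte {name}: non-finite {attr}")
            if blk.b_true < 0:
                raise ValueError(f"analyte {name}: b_true must be >= 0")
            if blk.sigma_dose < 0 or blk.sigma_noise < 0:
                raise ValueError(f"analyte {name}: SDs must be >= 0")
            if not 0 <= blk.blood_coupling <= 1:
                raise ValueError(f"analyte {name}: blood_coupling must be in [0, 1]")
            if not 0 <= blk.nondetect_rate < 1:
                raise ValueError(f"analyte {name}: nondetect_rate must be in [0, 1)")
        for blk in (self.creatinine, self.osmolality):
            if blk.sigma < 0 or blk.b_true < 0 or not np.isfinite(blk.gm):
                raise ValueError("surrogate block invalid")
        for label, props in (("gender", self.gender_proportions),
                             ("ethnicity", self.ethnicity_proportions)):
            if any(p < 0 for p in props.values()):
                raise ValueError(f"{label} proportions must be >= 0")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} proportions must sum to 1")
        band_p = [b[2] for b in self.age_bands]
        if any(p < 0 for p in band_p) or abs(sum(band_p) - 1.0) > 1e-9:
            raise ValueError("age-band proportions must be >= 0 and sum to 1")
        for rate in self.exclusion_rates.values():
            if not 0 <= rate < 1:
                raise ValueError("exclusion rates must be in [0, 1)")


def default_params(**overrides) -> SyntheticParams:
    """Default parameter set, optionally with top-level fields replaced."""
    return replace(SyntheticParams(), **overrides)


def _intercept(blk, ufr_mu: float) -> float:
    # ln C averages a − b·ufr_mu; solve for the target GM.
    return blk.a if blk.a is not None else math.log(blk.gm) + blk.b_true * ufr_mu


def _scr_at_egfr60(age: np.ndarray, female: np.ndarray, black: np.ndarray,
                   height: np.ndarray) -> np.ndarray:
    """Serum creatinine (mg/dL) at which eGFR equals exactly 60, per record.

    Adults: closed-form inversion of the 2009 CKD-EPI equation (monotone
    decreasing in creatinine).  Children (<18 y): Bedside Schwartz.
    """
    kappa = np.where(female, _KAPPA["female"], _KAPPA["male"])
    alpha = np.where(female, _ALPHA["female"], _ALPHA["male"])
    g0 = 141.0 * 0.993 ** age * np.where(female, 1.018, 1.0) * np.where(black, 1.159, 1.0)
    with np.errstate(invalid="ignore"):
        scr_hi = kappa * (g0 / 60.0) ** (1.0 / 1.209)       # g0 > 60 branch
        scr_lo = kappa * (60.0 / g0) ** (1.0 / alpha)       # g0 <= 60 branch
    scr_adult = np.where(g0 > 60.0, scr_hi, scr_lo)
    scr_child = 0.413 * height / 60.0
    return np.where(age < 18, scr_child, scr_adult)


def generate_cohort(params: SyntheticParams) -> Cohort:
    """Generate a synthetic cohort; identical params give an identical cohort."""
    params.validate()
    n = int(params.n)
    rng = np.random.default_rng(params.seed)

    # --- demographics ------------------------------------------------------
    genders = np.array(list(params.gender_proportions))
    gender = rng.choice(genders, size=n, p=list(params.gender_proportions.values()))
    eths = np.array(list(params.ethnicity_proportions))
    ethnicity = rng.choice(eths, size=n, p=list(params.ethnicity_proportions.values()))
    band_idx = rng.choice(len(params.age_bands), size=n,
                          p=[b[2] for b in params.age_bands])
    lo = np.array([b[0] for b in params.age_bands])[band_idx].astype(float)
    hi = np.array([b[1] for b in params.age_bands])[band_idx].astype(float)
    age = rng.uniform(lo, hi + 1.0)  # uniform within band, [lo, hi+1)
    h_mu, h_sd = (np.array([params.height_by_band[i][j] for i in band_idx])
                  for j in (0, 1))
    height = np.clip(rng.normal(h_mu, h_sd), 100.0, None)
    w_mu, w_sd = (np.array([params.weight_by_band[i][j] for i in band_idx])
                  for j in (0, 1))
    bodyweight = np.clip(rng.normal(w_mu, w_sd), 15.0, None)

    # --- hydration ---------------------------------------------------------
    ln_ufr = rng.normal(params.ufr_mu, params.ufr_sigma, size=n)
    ufr = np.exp(ln_ufr)
    void_time = rng.uniform(60.0, 240.0, size=n)  # min since previous void
    void_volume = ufr * void_time

    z_ufr = ((ln_ufr - params.ufr_mu) / params.ufr_sigma
             if params.ufr_sigma > 0 else np.zeros(n))

    # --- dilution surrogates ----------------------------------------------
    a_cr = _intercept(params.creatinine, params.ufr_mu)
    urine_creatinine = np.exp(a_cr - params.creatinine.b_true * ln_ufr
                              + rng.normal(0.0, params.creatinine.sigma, n))
    a_osm = _intercept(params.osmolality, params.ufr_mu)
    osmolality = np.exp(a_osm - params.osmolality.b_true * ln_ufr
                        + rng.normal(0.0, params.osmolality.sigma, n))

    # --- urinary analytes, latent doses, blood, non-detects ---------------
    cols: dict[str, np.ndarray] = {}
    detect: dict[str, np.ndarray] = {}
    lods: dict[str, float] = {}
    as_imm_vals = None
    for name, blk in params.analytes.items():
        a = _intercept(blk, params.ufr_mu)
        z_d = rng.standard_normal(n)
        rho_du = blk.dose_ufr_corr
        dose = blk.sigma_dose * (rho_du * z_ufr
                                 + math.sqrt(max(0.0, 1 - rho_du ** 2)) * z_d)
        eps = rng.normal(0.0, blk.sigma_noise, n)
        ln_c = a + dose - blk.b_true * ln_ufr + eps
        conc = np.exp(ln_c)

        sigma_tot = math.sqrt((blk.b_true * params.ufr_sigma) ** 2
                              + blk.sigma_dose ** 2 + blk.sigma_noise ** 2)
        if blk.lod is not None:
            lod = blk.lod
        elif blk.nondetect_rate > 0 and sigma_tot > 0:
            mu_tot = a - blk.b_true * params.ufr_mu
            lod = float(np.exp(mu_tot + norm.ppf(blk.nondetect_rate) * sigma_tot))
        else:
            lod = 0.0
        det = conc >= lod
        conc = np.where(det, conc, lod)  # placeholder at the limit, never 0

        if blk.blood_gm is not None:
            z_b = rng.standard_normal(n)
            rho = blk.blood_coupling
            dose_std = dose / blk.sigma_dose if blk.sigma_dose > 0 else np.zeros(n)
            ln_b = (math.log(blk.blood_gm)
                    + blk.blood_sigma * (rho * dose_std
                                         + math.sqrt(max(0.0, 1 - rho ** 2)) * z_b))
            cols[f"blood_{name}"] = np.exp(ln_b)

        if name == "as_imm":
            as_imm_vals, as_det, as_lod = conc, det, lod
        else:
            cols[f"urine_{name}"] = conc
            detect[f"detect_{name}"] = det
            lods[name] = lod

    if as_imm_vals is None:
        raise ValueError("params.analytes must include 'as_imm'")
    for sp, frac in SPECIES_FRACTIONS.items():
        cols[sp] = as_imm_vals * frac
        detect[f"detect_{sp}"] = np.ones(n, dtype=bool)
    cols["total_as"] = as_imm_vals / AS_IMM_SHARE_OF_TOTAL
    detect["detect_total_as"] = as_det
    lods["total_as"] = as_lod / AS_IMM_SHARE_OF_TOTAL

    # --- eligibility covariates -------------------------------------------
    rates = params.exclusion_rates
    # albuminuria: lognormal albumin-creatinine ratio with P(ACR > 30) = rate
    sigma_acr = 1.0
    rate_alb = rates.get("albuminuria", 0.0)
    mu_acr = (math.log(30.0) - norm.ppf(1.0 - rate_alb) * sigma_acr
              if rate_alb > 0 else math.log(30.0) - 6.0 * sigma_acr)
    acr = np.exp(rng.normal(mu_acr, sigma_acr, n))
    urinary_albumin = acr * urine_creatinine  # mg/L = (mg/g) * (g/L)

    # diabetes: half self-report, half glucose-triggered (fasting >= 8 h)
    rate_dia = rates.get("diabetes", 0.0)
    dia_flag = rng.random(n) < rate_dia
    dia_self = dia_flag & (rng.random(n) < 0.5)
    dia_gluc = dia_flag & ~dia_self
    fasting_hours = rng.uniform(3.0, 14.0, n)
    fasting_hours[dia_gluc] = rng.uniform(8.0, 14.0, int(dia_gluc.sum()))
    plasma_glucose = np.clip(rng.normal(95.0, 10.0, n), 60.0, 124.0)
    plasma_glucose[dia_gluc] = rng.uniform(126.0, 300.0, int(dia_gluc.sum()))

    # CKD: half self-report, half eGFR-triggered via serum creatinine placed
    # on the correct side of the eGFR = 60 boundary
    rate_ckd = rates.get("ckd", 0.0)
    ckd_flag = rng.random(n) < rate_ckd
    ckd_self = ckd_flag & (rng.random(n) < 0.5)
    ckd_egfr = ckd_flag & ~ckd_self
    scr60 = _scr_at_egfr60(age, gender == "female",
                           ethnicity == "non-Hispanic black", height)
    scr_mult = rng.uniform(0.45, 0.85, n)
    scr_mult[ckd_egfr] = rng.uniform(1.15, 1.80, int(ckd_egfr.sum()))
    serum_creatinine = scr60 * scr_mult

    df = pd.DataFrame({
        "sqn": np.arange(1, n + 1),
        "gender": gender,
        "ethnicity": ethnicity,
        "age": age,
        "bodyweight": bodyweight,
        "height": height,
        "void_volume": void_volume,
        "void_time": void_time,
        "ufr": ufr,
        "urine_creatinine": urine_creatinine,
        "osmolality": osmolality,
        "urine_pb": cols["urine_pb"],
        "urine_cd": cols["urine_cd"],
        "urine_i": cols["urine_i"],
        "as3": cols["as3"],
        "as5": cols["as5"],
        "mma": cols["mma"],
        "dma": cols["dma"],
        "total_as": cols["total_as"],
        "blood_pb": cols["blood_pb"],
        "blood_cd": cols["blood_cd"],
        "urinary_albumin": urinary_albumin,
        "serum_creatinine": serum_creatinine,
        "plasma_glucose": plasma_glucose,
        "fasting_hours": fasting_hours,
        "selfreport_diabetes": dia_self,
        "selfreport_ckd": ckd_self,
        "detect_pb": detect["detect_pb"],
        "detect_cd": detect["detect_cd"],
        "detect_i": detect["detect_i"],
        "detect_total_as": detect["detect_total_as"],
        "detect_as3": detect["detect_as3"],
        "detect_as5": detect["detect_as5"],
        "detect_mma": detect["detect_mma"],
        "detect_dma": detect["detect_dma"],
    })
    for col in ("selfreport_diabetes", "selfreport_ckd", "detect_pb", "detect_cd",
                "detect_i", "detect_total_as", "detect_as3", "detect_as5",
                "detect_mma", "detect_dma"):
        df[col] = df[col].astype("boolean")
    return Cohort(df, provenance={"source": "synthetic", "seed": int(params.seed),
                                  "lod": lods})
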