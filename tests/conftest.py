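import dataclasses

import numpy as np
import pandas as pd
import pytest

from urinadjust.cohort import Cohort
from urinadjust.synthetic import AnalyteParams, SyntheticParams, default_params

#: Template volunteer: healthy adult, all analytes detected, eGFR well
#: above 60, no exclusion triggers.
RECORD_DEFAULTS = dict(
    gender="male", ethnicity="non-Hispanic white", age=30.0, bodyweight=80.0,
    height=175.0, void_volume=105.0, void_time=150.0, ufr=0.7,
    urine_creatinine=1.1, osmolality=635.0, urine_pb=0.5, urine_cd=0.2,
    urine_i=149.0, as3=0.88, as5=0.38, mma=1.13, dma=3.9, total_as=7.9,
    blood_pb=1.1, blood_cd=0.3, urinary_albumin=10.0, serum_creatinine=0.8,
    plasma_glucose=95.0, fasting_hours=10.0, selfreport_diabetes=False,
    selfreport_ckd=False, detect_pb=True, detect_cd=True, detect_i=True,
    detect_total_as=True, detect_as3=True, detect_as5=True, detect_mma=True,
    detect_dma=True,
)

BOOL_COLS = [k for k, v in RECORD_DEFAULTS.items() if isinstance(v, bool)]


def make_cohort(overrides_per_record, provenance=None):
    """Build a small cohort from a list of per-record override dicts."""
    rows = []
    for i, ov in enumerate(overrides_per_record, start=1):
        row = {"sqn": i, **RECORD_DEFAULTS, **ov}
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in BOOL_COLS:
        df[col] = df[col].astype("boolean")
    return Cohort(df, provenance=provenance or {})


@pytest.fixture
def tiny_cohort():
    """Three clean records with distinct hydration levels."""
    return make_cohort([
        {"ufr": 0.35, "void_volume": 52.5, "osmolality": 900.0, "urine_pb": 0.9},
        {"ufr": 0.70, "void_volume": 105.0},
        {"ufr": 1.40, "void_volume": 210.0, "osmolality": 380.0, "urine_pb": 0.3},
    ])


def quiet_params(n=200, seed=0, **kwargs):
    """Synthetic parameters with exclusions and censoring switched off, so
    every generated record survives the cascade."""
    base = default_params(n=n, seed=seed, **kwargs)
    analytes = {k: dataclasses.replace(v, nondetect_rate=0.0)
                for k, v in base.analytes.items()}
    return dataclasses.replace(
        base, analytes=analytes,
        exclusion_rates={"albuminuria": 0.0, "diabetes": 0.0, "ckd": 0.0})


def noiseless_params(n=100, seed=0):
    """Deterministic dilution: sigma_dose = sigma_noise = 0 for all analytes."""
    base = quiet_params(n=n, seed=seed)
    analytes = {k: dataclasses.replace(v, sigma_dose=0.0, sigma_noise=0.0)
                for k, v in base.analytes.items()}
    return dataclasses.replace(base, analytes=analytes)
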