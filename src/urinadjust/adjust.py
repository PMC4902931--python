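"""Hydration-adjustment transforms for spot-urine analyte concentrations.

Methods
-------
unadjusted          C (μg/L), passed through
creatinine          C / C_cr (μg/g creatinine)
osmolality          C · Osm_ref / Osm_meas (μg/L at the reference osmolality;
                    Levine-Fahy form)
er                  excretion rate, C · V / t (ng/hr)
erbw                bodyweight-normalised excretion rate (ng/kg-hr)
ufr_power           C · UFR^b (μg/L at the standard UFR of 1 mL/min), with an
                    analyte-specific exponent b

All transforms are per-record (no cohort state), hence commute with
subsetting, and are equivariant under rescaling of the input concentration.
μg/L ≡ ng/mL is exploited by the excretion-rate formula; with UFR in mL/min
this makes ER = 60 · C · UFR when expressed per hour.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .cohort import Cohort, SPECIES_COLUMNS

__all__ = [
    "ufr_from_void", "excretion_rate", "excretion_rate_bw", "creatinine_adjust",
    "osmolality_adjust", "ufr_power_adjust", "as_imm", "adjust_cohort",
    "analyte_concentration", "METHODS", "DEFAULT_ANALYTES",
    "MIN_PER_HOUR", "DEFAULT_OSM_REF",
]

#: Minutes per hour — converts UFR (mL/min) to the per-hour excretion scale.
MIN_PER_HOUR = 60.0

#: Documented fallback reference osmolality (mOsm/kg), used when no training
#: cohort is available to compute a median from.
DEFAULT_OSM_REF = 734.0

METHODS = ("unadjusted", "creatinine", "osmolality", "er", "erbw", "ufr_power")
DEFAULT_ANALYTES = ("pb", "cd", "as_imm", "i")

_CONC_COLUMN = {"pb": "urine_pb", "cd": "urine_cd", "i": "urine_i",
                "creatinine": "urine_creatinine", "total_as": "total_as"}

_UNITS = {"unadjusted": "ug/L",
          "creatinine": "ug/g creatinine",
          "osmolality": "ug/L at reference osmolality",
          "er": "ng/hr",
          "erbw": "ng/kg-hr",
          "ufr_power": "ug/L at UFR 1 mL/min"}


def _positive(name, x):
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be strictly positive and finite")
    return arr


def _maybe_scalar(x):
    return float(x) if np.ndim(x) == 0 else x


def ufr_from_void(volume, time=None):
    """Urinary flow rate V/t in mL/min.

    Either elementwise ``ufr_from_void(volume_mL, time_min)`` or a composite
    over several voids, ``ufr_from_void([(v1, t1), (v2, t2), ...])``, which
    pools total volume over total time.
    """
    if time is None:
        pairs = np.asarray(volume, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("composite form requires a list of (volume, time) pairs")
        v = _positive("volume", pairs[:, 0]).sum()
        t = _positive("time", pairs[:, 1]).sum()
        return float(v / t)
    v = _positive("volume", volume)
    t = _positive("time", time)
    return _maybe_scalar(v / t)


def excretion_rate(c_vol, volume, time):
    """Excretion rate (C · V)/t in ng/hr (C in μg/L ≡ ng/mL, V mL, t hours)."""
    c = _positive("c_vol", c_vol)
    v = _positive("volume", volume)
    t = _positive("time", time)
    return _maybe_scalar(c * v / t)


def excretion_rate_bw(c_vol, volume, time, bodyweight):
    """Bodyweight-normalised excretion rate (C · V)/(t · BW) in ng/kg-hr."""
    bw = _positive("bodyweight", bodyweight)
    return _maybe_scalar(np.asarray(excretion_rate(c_vol, volume, time)) / bw)


def creatinine_adjust(c_vol, c_cr):
    """Creatinine-adjusted concentration C / C_cr in μg/g creatinine."""
    c = _positive("c_vol", c_vol)
    cr = _positive("c_cr", c_cr)
    return _maybe_scalar(c / cr)


def osmolality_adjust(c_vol, osm_meas, osm_ref=DEFAULT_OSM_REF):
    """Osmolality-adjusted concentration C · Osm_ref / Osm_meas (μg/L)."""
    c = _positive("c_vol", c_vol)
    osm = _positive("osm_meas", osm_meas)
    ref = _positive("osm_ref", osm_ref)
    return _maybe_scalar(c * ref / osm)


def ufr_power_adjust(c_vol, ufr, b):
    """Flow-rate power adjustment C · UFR^b (μg/L at UFR = 1 mL/min).

    ``b`` may be any finite value here; the derivation grid's [0, 1.5]
    constraint belongs to the optimiser, not the transform.
    """
    c = _positive("c_vol", c_vol)
    u = _positive("ufr", ufr)
    barr = np.asarray(b, dtype=float)
    if np.any(~np.isfinite(barr)):
        raise ValueError("b must be finite")
    return _maybe_scalar(c * u ** barr)


def as_imm(as3, as5, mma, dma, detect=None, policy="as-is"):
    """Inorganic-plus-methylated arsenic: As(III) + As(V) + MMA + DMA (μg/L).

    Arsenobetaine is never included.  ``detect`` is an optional 4-tuple of
    detection flags aligned with the species arguments; species flagged
    non-detect carry their detection limit as the stored value and enter the
    sum under ``policy``: "as-is" (at the limit, default), "lod/sqrt2", or
    "zero".
    """
    species = [np.asarray(s, dtype=float) for s in (as3, as5, mma, dma)]
    if all(np.all(np.isnan(s)) for s in species):
        raise ValueError("all four arsenic species are missing")
    if policy not in ("as-is", "lod/sqrt2", "zero"):
        raise ValueError(f"unknown non-detect policy: {policy!r}")
    if detect is None:
        detect = [np.ones_like(s, dtype=bool) for s in species]
    else:
        detect = [np.asarray(d, dtype=bool) for d in detect]
    total = np.zeros(np.broadcast(*species).shape)
    for s, d in zip(species, detect):
        if policy == "as-is":
            contrib = s
        elif policy == "lod/sqrt2":
            contrib = np.where(d, s, s / np.sqrt(2.0))
        else:
            contrib = np.where(d, s, 0.0)
        total = total + contrib
    return _maybe_scalar(total)


def analyte_concentration(data, analyte, nondetect_policy="as-is"):
    """Volume-based concentration series for one analyte from a cohort table."""
    df = data.data if isinstance(data, Cohort) else data
    if analyte == "as_imm":
        detect = tuple(df[f"detect_{sp}"].fillna(True).to_numpy(dtype=bool)
                       for sp in SPECIES_COLUMNS)
        return np.asarray(as_imm(*(df[sp].to_numpy(float) for sp in SPECIES_COLUMNS),
                                 detect=detect, policy=nondetect_policy))
    try:
        col = _CONC_COLUMN[analyte]
    except KeyError:
        raise KeyError(f"unknown analyte: {analyte!r}") from None
    return df[col].to_numpy(float)


def adjust_cohort(cohort, method, b=None, osm_ref=None,
                  analytes=DEFAULT_ANALYTES, nondetect_policy="as-is") -> pd.DataFrame:
    """Apply one adjustment method to every record × analyte.

    Returns a long-format DataFrame: sqn, analyte, method, value, units,
    and where applicable b_used / osm_ref_used.

    ``b`` (ufr_power only) is a scalar or an ``{analyte: b}`` mapping;
    ``osm_ref`` (osmolality only) defaults to the cohort's own median
    osmolality when not given.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method: {method!r}")
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    frames = []
    if method == "osmolality" and osm_ref is None:
        osm_ref = float(np.median(df["osmolality"].to_numpy(float)))
    for analyte in analytes:
        c = analyte_concentration(df, analyte, nondetect_policy)
        row = {"sqn": df["sqn"].to_numpy(), "analyte": analyte, "method": method,
               "units": _UNITS[method]}
        if method == "unadjusted":
            row["value"] = np.asarray(c, dtype=float)
        elif method == "creatinine":
            row["value"] = creatinine_adjust(c, df["urine_creatinine"].to_numpy(float))
        elif method == "osmolality":
            row["value"] = osmolality_adjust(c, df["osmolality"].to_numpy(float), osm_ref)
            row["osm_ref_used"] = osm_ref
        elif method in ("er", "erbw"):
            t_hr = df["void_time"].to_numpy(float) / MIN_PER_HOUR
            if method == "er":
                row["value"] = excretion_rate(c, df["void_volume"].to_numpy(float), t_hr)
            else:
                if df["bodyweight"].isna().any():
                    raise ValueError("erbw requires bodyweight for every record")
                row["value"] = excretion_rate_bw(c, df["void_volume"].to_numpy(float),
                                                 t_hr, df["bodyweight"].to_numpy(float))
        else:  # ufr_power
            if b is None:
                raise ValueError("ufr_power requires b (scalar or per-analyte mapping)")
            b_k = b if isinstance(b, numbers.Number) else b.get(analyte)
            if b_k is None:
                raise ValueError(f"no b value provided for analyte {analyte!r}")
            row["value"] = ufr_power_adjust(c, df["ufr"].to_numpy(float), b_k)
            row["b_used"] = float(b_k)
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)
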