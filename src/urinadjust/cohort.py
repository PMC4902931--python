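"""Cohort container and tabular I/O.

A cohort is one row per volunteer, keyed by a sequence number (``sqn``),
carrying demographics, spot-urine chemistry (creatinine, osmolality, void
volume/time and the derived urinary flow rate), urinary and blood analyte
concentrations, detection flags, and the covariates needed by the
eligibility rules (albumin, serum creatinine, plasma glucose, self-reported
conditions).

The on-disk format is a plain CSV with one header row, snake_case column
names, booleans written as 0/1 and missing values as empty cells.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_xpt_mapped",
    "MANDATORY_COLUMNS",
    "URINARY_ANALYTES",
    "SPECIES_COLUMNS",
]

#: Urinary analytes carried per record (concentration columns, μg/L).
URINARY_ANALYTES = ("urine_pb", "urine_cd", "urine_i", "total_as")

#: Arsenic species columns summed into As_IMM (arsenobetaine excluded).
SPECIES_COLUMNS = ("as3", "as5", "mma", "dma")

#: Boolean columns, serialized as 0/1.
BOOL_COLUMNS = (
    "selfreport_diabetes",
    "selfreport_ckd",
    "detect_pb",
    "detect_cd",
    "detect_i",
    "detect_total_as",
    "detect_as3",
    "detect_as5",
    "detect_mma",
    "detect_dma",
)

#: Strictly positive when present.
POSITIVE_COLUMNS = (
    "age",
    "bodyweight",
    "height",
    "void_volume",
    "void_time",
    "ufr",
    "urine_creatinine",
    "osmolality",
    "urine_pb",
    "urine_cd",
    "urine_i",
    "as3",
    "as5",
    "mma",
    "dma",
    "total_as",
    "blood_pb",
    "blood_cd",
    "urinary_albumin",
    "serum_creatinine",
    "plasma_glucose",
)

MANDATORY_COLUMNS = (
    ("sqn", "gender", "ethnicity", "age", "bodyweight", "height",
     "void_volume", "void_time", "ufr", "urine_creatinine", "osmolality")
    + URINARY_ANALYTES
    + SPECIES_COLUMNS
    + ("blood_pb", "blood_cd", "urinary_albumin", "serum_creatinine",
       "plasma_glucose", "fasting_hours")
    + BOOL_COLUMNS
)

GENDERS = ("male", "female")
ETHNICITIES = ("non-Hispanic white", "non-Hispanic black", "Mexican American")

#: Relative tolerance for the UFR = void_volume / void_time consistency check.
UFR_CONSISTENCY_RTOL = 1e-6


class CohortValidationError(ValueError):
    """A cohort table violates the column dictionary or a value constraint."""


@dataclass
class Cohort:
    """Ordered collection of volunteer records with an audit trail.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per volunteer; columns per the column dictionary.
    audit : list
        Per-stage removal records (appended by the eligibility filters).
    provenance : dict
        Free-form source tags, e.g. ``{"source": "synthetic", "seed": 7,
        "split": "training"}``.
    """

    data: pd.DataFrame
    audit: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    validation_warnings: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def sqns(self) -> np.ndarray:
        return self.data["sqn"].to_numpy()

    def subset(self, sqns: Iterable, provenance_update: dict | None = None) -> "Cohort":
        """Return the sub-cohort with the given sequence numbers, in cohort order."""
        keep = self.data["sqn"].isin(list(sqns))
        prov = dict(self.provenance)
        if provenance_update:
            prov.update(provenance_update)
        return Cohort(self.data.loc[keep].reset_index(drop=True),
                      audit=list(self.audit), provenance=prov)

    def validate(self) -> None:
        """Raise :class:`CohortValidationError` on any contract violation."""
        df = self.data
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing mandatory column(s): {', '.join(missing)}")
        if df["sqn"].duplicated().any():
            dups = df.loc[df["sqn"].duplicated(), "sqn"].tolist()
            raise CohortValidationError(f"duplicate sqn values: {dups}")
        for col in POSITIVE_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.loc[vals.notna() & (vals <= 0), "sqn"].tolist()
            if bad:
                raise CohortValidationError(
                    f"non-positive values in column '{col}' for sqn: {bad}")
        bad_gender = set(df["gender"].dropna()) - set(GENDERS)
        if bad_gender:
            raise CohortValidationError(f"unknown gender values: {sorted(bad_gender)}")
        bad_eth = set(df["ethnicity"].dropna()) - set(ETHNICITIES)
        if bad_eth:
            raise CohortValidationError(f"unknown ethnicity values: {sorted(bad_eth)}")
        self._check_ufr_consistency()
        # audit reconciliation: initial − Σ removed == current
        if self.audit:
            initial = self.audit[0].get("input") if isinstance(self.audit[0], dict) \
                else getattr(self.audit[0], "removed", 0) + getattr(self.audit[0], "remaining", 0)
            removed = sum((a.get("removed") if isinstance(a, dict) else a.removed)
                          for a in self.audit)
            if initial is not None and initial - removed != self.n:
                raise CohortValidationError(
                    f"audit does not reconcile: initial {initial} - removed {removed} "
                    f"!= current {self.n}")

    def _check_ufr_consistency(self) -> None:
        df = self.data
        v = pd.to_numeric(df["void_volume"], errors="coerce")
        t = pd.to_numeric(df["void_time"], errors="coerce")
        u = pd.to_numeric(df["ufr"], errors="coerce")
        ok = v.notna() & t.notna() & u.notna() & (t > 0)
        mismatch = ok & (np.abs(u - v / t) > UFR_CONSISTENCY_RTOL * np.abs(u).clip(lower=1e-30))
        for sqn in df.loc[mismatch, "sqn"]:
            msg = f"sqn {sqn}: ufr inconsistent with void_volume/void_time"
            self.validation_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)


def _serialize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in BOOL_COLUMNS:
        if col in out.columns:
            s = out[col]
            out[col] = s.map(lambda x: "" if pd.isna(x) else str(int(bool(x))))
    return out


def write_cohort(cohort: Cohort, destination) -> None:
    """Write a cohort to CSV (UTF-8, LF line endings, booleans as 0/1).

    Numeric text is written at full ``repr`` precision so that a read/write
    round trip reproduces every value bit-exactly.
    """
    df = _serialize(cohort.data)
    text = df.to_csv(index=False, lineterminator="\n",
                     float_format=lambda x: repr(float(x)))
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)


def cohort_to_csv_bytes(cohort: Cohort) -> bytes:
    buf = io.StringIO()
    write_cohort(cohort, buf)
    return buf.getvalue().encode("utf-8")


def read_cohort(source, strict: bool = True, provenance: dict | None = None) -> Cohort:
    """Read a cohort CSV, validating against the column dictionary.

    Parameters
    ----------
    source : path or file-like
    strict : bool
        When True (default), unknown columns are rejected; when False they
        are preserved untouched.
    """
    df = pd.read_csv(source)
    unknown = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    if unknown and strict:
        raise CohortValidationError(f"unknown column(s): {', '.join(unknown)}")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in BOOL_COLUMNS:
        df[col] = df[col].map(lambda x: pd.NA if pd.isna(x) else bool(int(x)))
        df[col] = df[col].astype("boolean")
    cohort = Cohort(df, provenance=provenance or {})
    cohort.validate()
    return cohort


def read_xpt_mapped(xpt_path, mapping: dict[str, str], **kwargs) -> pd.DataFrame:
    """Ingest a SAS transport (.xpt) file with a user-supplied column mapping.

    ``mapping`` maps source variable names to column-dictionary names; no
    source names are hardcoded here.  Returns the renamed DataFrame — the
    caller assembles a full cohort (typically merging several files on the
    sequence number) before constructing a :class:`Cohort`.
    """
    df = pd.read_sas(xpt_path, format="xport", **kwargs)
    present = {src: dst for src, dst in mapping.items() if src in df.columns}
    absent = set(mapping) - set(present)
    if absent:
        raise CohortValidationError(
            f"mapped variable(s) not present in transport file: {sorted(absent)}")
    return df[list(present)].rename(columns=present)
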