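"""scikit-learn style transformers over cohort tables.

Each adjuster consumes a cohort table (a :class:`~urinadjust.cohort.Cohort`
or a DataFrame following its column dictionary) and returns a DataFrame of
adjusted concentrations, one column per analyte.  They compose with sklearn
pipelines and model selection: parameters are exposed through
``get_params``/``set_params``, state learned in ``fit`` lives in
trailing-underscore attributes, and transforms are stateless per record.

:class:`UFRPowerAdjuster` is the estimator whose fit actually learns
something: the analyte-specific flow-rate exponent b, derived on the
training cohort by the 0–1.5/0.01 grid search under criterion A (minimal
|r| against UFR) or criterion B (maximal r against blood).
:class:`OsmolalityAdjuster` learns the reference osmolality (training
median) when ``osm_ref="auto"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import araki
from .adjust import (DEFAULT_ANALYTES, DEFAULT_OSM_REF, MIN_PER_HOUR,
                     analyte_concentration)
from .cohort import Cohort

__all__ = ["UnadjustedBaseline", "CreatinineAdjuster", "OsmolalityAdjuster",
           "ExcretionRateAdjuster", "UFRPowerAdjuster"]


def _frame(X) -> pd.DataFrame:
    return X.data if isinstance(X, Cohort) else X


class _CohortAdjuster(TransformerMixin, BaseEstimator):
    """Shared plumbing: analyte selection and wide-format output."""

    def __init__(self, analytes=DEFAULT_ANALYTES, nondetect_policy="as-is"):
        self.analytes = analytes
        self.nondetect_policy = nondetect_policy

    def fit(self, X, y=None):
        _frame(X)  # presence check only; stateless by default
        self.is_fitted_ = True
        return self

    def _concentrations(self, df: pd.DataFrame) -> dict[str, np.ndarray]:
        return {a: analyte_concentration(df, a, self.nondetect_policy)
                for a in self.analytes}

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        df = _frame(X)
        out = {a: self._adjust_one(df, c) for a, c in self._concentrations(df).items()}
        return pd.DataFrame(out, index=df.index)

    def _adjust_one(self, df, c):  # pragma: no cover - abstract
        raise NotImplementedError


class UnadjustedBaseline(_CohortAdjuster):
    """Pass-through of volume-based concentrations (μg/L)."""

    def _adjust_one(self, df, c):
        return np.asarray(c, dtype=float)


class CreatinineAdjuster(_CohortAdjuster):
    """C / C_cr, μg/g creatinine."""

    def _adjust_one(self, df, c):
        return c / df["urine_creatinine"].to_numpy(float)


class OsmolalityAdjuster(_CohortAdjuster):
    """C · Osm_ref / Osm_meas (Levine-Fahy form).

    ``osm_ref="auto"`` learns the training cohort's median osmolality in
    ``fit``; a numeric value fixes the reference (the documented fallback
    constant is 734 mOsm/kg).
    """

    def __init__(self, analytes=DEFAULT_ANALYTES, nondetect_policy="as-is",
                 osm_ref="auto"):
        super().__init__(analytes=analytes, nondetect_policy=nondetect_policy)
        self.osm_ref = osm_ref

    def fit(self, X, y=None):
        df = _frame(X)
        if self.osm_ref == "auto":
            self.osm_ref_ = float(np.median(df["osmolality"].to_numpy(float)))
        elif self.osm_ref is None:
            self.osm_ref_ = DEFAULT_OSM_REF
        else:
            self.osm_ref_ = float(self.osm_ref)
        if self.osm_ref_ <= 0:
            raise ValueError("reference osmolality must be positive")
        self.is_fitted_ = True
        return self

    def _adjust_one(self, df, c):
        return c * self.osm_ref_ / df["osmolality"].to_numpy(float)


class ExcretionRateAdjuster(_CohortAdjuster):
    """Excretion rate (C·V)/t in ng/hr; per-bodyweight variant in ng/kg-hr."""

    def __init__(self, analytes=DEFAULT_ANALYTES, nondetect_policy="as-is",
                 per_bodyweight=False):
        super().__init__(analytes=analytes, nondetect_policy=nondetect_policy)
        self.per_bodyweight = per_bodyweight

    def _adjust_one(self, df, c):
        t_hr = df["void_time"].to_numpy(float) / MIN_PER_HOUR
        er = c * df["void_volume"].to_numpy(float) / t_hr
        if self.per_bodyweight:
            er = er / df["bodyweight"].to_numpy(float)
        return er


class UFRPowerAdjuster(_CohortAdjuster):
    """Analyte-specific flow-rate power adjustment C · UFR^b.

    ``fit`` grid-derives b per analyte on the training cohort (criterion
    "A": minimal |r| of the adjusted concentration against ln UFR;
    criterion "B": maximal r against the ln blood concentration — available
    only for analytes with paired blood measurements).  Fitted attributes:
    ``b_`` (dict analyte → exponent), ``profiles_`` (full grid profiles) and
    ``b_table_`` (tidy summary).  A pre-specified ``b`` mapping skips the
    derivation.  Cohorts tagged as the testing split are refused during fit
    unless ``allow_testing=True``.
    """

    def __init__(self, analytes=DEFAULT_ANALYTES, nondetect_policy="as-is",
                 criterion="A", grid=araki.DEFAULT_GRID, b=None,
                 allow_testing=False):
        super().__init__(analytes=analytes, nondetect_policy=nondetect_policy)
        self.criterion = criterion
        self.grid = grid
        self.b = b
        self.allow_testing = allow_testing

    def fit(self, X, y=None):
        if self.b is not None:
            self.b_ = dict(self.b)
            self.profiles_ = []
            self.b_table_ = pd.DataFrame(
                [{"analyte": a, "criterion": "fixed", "b_opt": v}
                 for a, v in self.b_.items()])
        else:
            cohort = X if isinstance(X, Cohort) else Cohort(_frame(X))
            table, profiles = araki.derive_b_table(
                cohort, criterion=self.criterion, analytes=self.analytes,
                grid=self.grid, nondetect_policy=self.nondetect_policy,
                allow_testing=self.allow_testing)
            self.b_ = dict(zip(table["analyte"], table["b_opt"]))
            self.profiles_ = profiles
            self.b_table_ = table
        self.is_fitted_ = True
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        df = _frame(X)
        ufr = df["ufr"].to_numpy(float)
        out = {}
        for a in self.analytes:
            if a not in self.b_:
                continue  # e.g. criterion B with no blood pair
            c = analyte_concentration(df, a, self.nondetect_policy)
            out[a] = c * ufr ** float(self.b_[a])
        return pd.DataFrame(out, index=df.index)
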