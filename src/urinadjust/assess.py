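"""Statistical assessment of adjustment methods.

The battery: an 80:20 train/test partition, geometric means with ranges,
Pearson correlation on natural-log transformed data with t-based p-values
and Fisher-z 95% confidence intervals, the Hotelling–Williams test for the
difference of two dependent correlations sharing a variable, a compact
letter display (methods share a letter iff their pairwise Williams test is
non-significant), and per-criterion method rankings:

* criterion A — |r| of the adjusted concentration against UFR, smaller is
  better (the shared variable in pairwise tests is ln UFR);
* criterion B — signed r against the blood concentration of the same
  analyte, larger is better (shared variable: ln blood).

ln-scale Pearson correlation is invariant to multiplicative unit changes,
so μg/dL blood versus μg/L urine needs no conversion, and method rankings
are unaffected by rescaling any analyte's units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import (DEFAULT_ANALYTES, MIN_PER_HOUR, adjust_cohort,
                     analyte_concentration)
from .araki import SplitLeakageError
from .cohort import Cohort

__all__ = ["CohortSplit", "CorrelationReport", "WilliamsResult", "split_cohort",
           "geometric_mean", "ln_pearson", "williams_test", "letter_groups",
           "evaluate_methods", "reports_to_frame", "gm_table",
           "compact_letter_display"]

_BLOOD_COLUMN = {"pb": "blood_pb", "cd": "blood_cd"}

#: Normal quantile used for the two-sided 95% Fisher-z interval.
Z_95 = 1.96


@dataclass
class CohortSplit:
    training_sqns: np.ndarray
    testing_sqns: np.ndarray
    fraction: float
    seed: int

    def apply(self, cohort: Cohort) -> tuple[Cohort, Cohort]:
        train = cohort.subset(self.training_sqns, {"split": "training"})
        test = cohort.subset(self.testing_sqns, {"split": "testing"})
        return train, test


@dataclass
class CorrelationReport:
    method: str
    analyte: str
    criterion: str
    r_p: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    letter_group: str = ""
    degenerate: bool = False


@dataclass
class WilliamsResult:
    t_statistic: float
    df: int
    p_value: float
    r12: float
    r13: float
    r23: float
    n: int


def split_cohort(cohort: Cohort, fraction: float = 0.8, seed: int = 0,
                 stratify_by=None) -> CohortSplit:
    """Random train/test partition of the cohort's sequence numbers.

    The training size is round(fraction · n) under round-half-even.  With
    ``stratify_by`` (a column name or list of names) the same rule is applied
    within each stratum, preserving the covariate distribution across splits.
    Deterministic for a given seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    df = cohort.data
    n = len(df)
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        n_train = round(fraction * n)
        if n_train < 2 or n - n_train < 2:
            raise ValueError("cohort too small for both splits to have >= 2 records")
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
    else:
        cols = [stratify_by] if isinstance(stratify_by, str) else list(stratify_by)
        parts = []
        for _, grp in df.groupby(cols, sort=True):
            idx = grp.index.to_numpy()
            k = round(fraction * len(idx))
            parts.append(rng.permutation(idx)[:k])
        train_idx = np.sort(np.concatenate(parts)) if parts else np.array([], int)
        if len(train_idx) < 2 or n - len(train_idx) < 2:
            raise ValueError("cohort too small for both splits to have >= 2 records")
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    sqn = df["sqn"].to_numpy()
    return CohortSplit(training_sqns=sqn[mask], testing_sqns=sqn[~mask],
                       fraction=fraction, seed=seed)


def geometric_mean(x) -> tuple[float, tuple[float, float]]:
    """Geometric mean exp(mean(ln x)) with the (min, max) range."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("empty vector")
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("geometric mean requires strictly positive finite values")
    return float(np.exp(np.mean(np.log(arr)))), (float(arr.min()), float(arr.max()))


def ln_pearson(x, y) -> CorrelationReport:
    """Pearson correlation of ln x with ln y, with p-value and 95% CI.

    p is two-sided from t = r·sqrt((n−2)/(1−r²)) on n−2 df; the CI is the
    Fisher-z interval z ± 1.96/sqrt(n−3), back-transformed.  |r| = 1 yields
    a degenerate interval and is flagged.
    """
    lx = np.log(np.asarray(x, dtype=float))
    ly = np.log(np.asarray(y, dtype=float))
    if not (np.all(np.isfinite(lx)) and np.all(np.isfinite(ly))):
        raise ValueError("inputs must be strictly positive and finite")
    n = len(lx)
    if len(ly) != n:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.var(lx) == 0 or np.var(ly) == 0:
        raise ValueError("zero variance after ln transform")
    r = float(np.corrcoef(lx, ly)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:  # exact collinearity up to rounding
        r = math.copysign(1.0, r)
        return CorrelationReport("", "", "", r_p=r, ci_low=r, ci_high=r,
                                 p_value=0.0, n=n, degenerate=True)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    z = np.arctanh(r)
    half = Z_95 / np.sqrt(n - 3)
    return CorrelationReport("", "", "", r_p=r, ci_low=float(np.tanh(z - half)),
                             ci_high=float(np.tanh(z + half)), p_value=float(p), n=n)


def williams_test(r12, r13, r23, n) -> WilliamsResult:
    """Hotelling–Williams test for r12 vs r13 sharing variable 1.

    t = (r12 − r13) · sqrt[ (n−1)(1+r23) /
        (2·|R|·(n−1)/(n−3) + r̄²(1−r23)³) ],  df = n − 3,

    with |R| = 1 − r12² − r13² − r23² + 2·r12·r13·r23 and r̄ = (r12+r13)/2.
    Antisymmetric under swapping r12 and r13; t = 0 exactly when r12 = r13.
    """
    n = int(n)
    if n <= 3:
        raise ValueError("n must exceed 3")
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    det = 1.0 - r12 ** 2 - r13 ** 2 - r23 ** 2 + 2.0 * r12 * r13 * r23
    if det < -1e-12:
        raise ValueError("correlation triple is not positive semidefinite")
    det = max(det, 0.0)
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * det * (n - 1) / (n - 3) + rbar ** 2 * (1.0 - r23) ** 3
    if denom <= 0:
        t = 0.0 if r12 == r13 else np.inf * np.sign(r12 - r13)
    else:
        t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    p = float(2.0 * stats.t.sf(abs(t), n - 3)) if np.isfinite(t) else 0.0
    if r12 == r13:
        t, p = 0.0, 1.0
    return WilliamsResult(t_statistic=float(t), df=n - 3, p_value=p,
                          r12=r12, r13=r13, r23=r23, n=n)


def _insert_absorb(n_items: int, significant) -> list[set]:
    """Compact-letter-display partition: start with one letter covering all
    items, split on each significant pair, absorb redundant subsets."""
    letters = [set(range(n_items))]
    for i in range(n_items):
        for j in range(i + 1, n_items):
            if not significant(i, j):
                continue
            new = []
            for L in letters:
                if i in L and j in L:
                    new.extend([L - {i}, L - {j}])
                else:
                    new.append(L)
            letters = []
            for L in new:  # absorb subsets (and duplicates)
                if L and not any(L < M or (L == M and L is not M) for M in new):
                    if L not in letters:
                        letters.append(L)
    return letters


def compact_letter_display(n_items: int, significant) -> list[set]:
    """Partition ``range(n_items)`` into letter sets given a pairwise
    significance predicate: items share a letter iff some returned set
    contains both, and that holds exactly for non-significant pairs."""
    return _insert_absorb(n_items, significant)


def letter_groups(reports: list[CorrelationReport], between_r: np.ndarray,
                  alpha: float = 0.05) -> list[CorrelationReport]:
    """Assign compact letter display labels to a set of method reports.

    All reports must share the analyte, criterion, sample size and the common
    third variable; ``between_r[i, j]`` is the ln-scale correlation between
    the adjusted series of methods i and j (the r23 of the pairwise Williams
    test).  Two methods share a letter iff their pairwise Williams p ≥ alpha.
    Letters are assigned best-method-first: increasing |r| for criterion A,
    decreasing r for criterion B.
    """
    if not reports:
        return reports
    ns = {rep.n for rep in reports}
    if len(ns) != 1:
        raise ValueError("all reports must share the same n")
    n = ns.pop()
    crit = reports[0].criterion
    m = len(reports)
    between_r = np.asarray(between_r, dtype=float)
    if between_r.shape != (m, m):
        raise ValueError("between_r must be an m x m matrix aligned with reports")

    def significant(i: int, j: int) -> bool:
        if i == j:
            return False
        if between_r[i, j] >= 1.0 - 1e-12:
            return False  # numerically identical adjusted series
        res = williams_test(reports[i].r_p, reports[j].r_p, between_r[i, j], n)
        return res.p_value < alpha

    letters = _insert_absorb(m, significant)
    if crit == "A":
        order = sorted(range(m), key=lambda i: abs(reports[i].r_p))
    else:
        order = sorted(range(m), key=lambda i: -reports[i].r_p)
    rank = {idx: pos for pos, idx in enumerate(order)}
    letters.sort(key=lambda L: min(rank[i] for i in L))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, rep in enumerate(reports):
        rep.letter_group = "".join(alphabet[k] for k, L in enumerate(letters) if i in L)
    return reports


def _ln_adjusted(cohort: Cohort, method: str, analyte: str, b_a, b_b, osm_ref,
                 nondetect_policy: str) -> np.ndarray:
    df = cohort.data
    c = analyte_concentration(df, analyte, nondetect_policy)
    lnC = np.log(c)
    lnU = np.log(df["ufr"].to_numpy(float))
    if method == "unadjusted":
        return lnC
    if method == "creatinine":
        return lnC - np.log(df["urine_creatinine"].to_numpy(float))
    if method == "osmolality":
        return lnC + np.log(osm_ref) - np.log(df["osmolality"].to_numpy(float))
    if method == "er":  # ln ER = ln C + ln UFR + ln 60
        return lnC + lnU + np.log(MIN_PER_HOUR)
    if method == "erbw":
        return lnC + lnU + np.log(MIN_PER_HOUR) - np.log(df["bodyweight"].to_numpy(float))
    if method == "ufra":
        return lnC + float(b_a[analyte]) * lnU
    if method == "ufrb":
        return lnC + float(b_b[analyte]) * lnU
    raise ValueError(f"unknown method: {method!r}")


def _check_b_provenance(table):
    if isinstance(table, pd.DataFrame) and table.attrs.get("split") == "testing":
        raise SplitLeakageError("b table was derived on the testing split; refusing")


def evaluate_methods(testing: Cohort, b_table_a, b_table_b=None, osm_ref=None,
                     analytes=DEFAULT_ANALYTES, alpha: float = 0.05,
                     nondetect_policy: str = "as-is"
                     ) -> tuple[list[CorrelationReport], dict]:
    """Score every adjustment method on the testing split.

    ``b_table_a`` / ``b_table_b`` are the criterion-A / criterion-B exponent
    tables derived on the *training* split (tables tagged as testing-derived
    are refused).  ``osm_ref`` defaults to the documented training-median
    convention and must be supplied by the caller; when None the testing
    cohort's own median is used with that caveat.

    Returns (reports, rankings): one report per method × analyte for
    criterion A, plus criterion B reports for analytes with blood pairs;
    rankings maps (analyte, criterion) to the method order, best first.
    """
    _check_b_provenance(b_table_a)
    _check_b_provenance(b_table_b)
    b_a = dict(zip(b_table_a["analyte"], b_table_a["b_opt"])) \
        if isinstance(b_table_a, pd.DataFrame) else dict(b_table_a or {})
    b_b = dict(zip(b_table_b["analyte"], b_table_b["b_opt"])) \
        if isinstance(b_table_b, pd.DataFrame) else dict(b_table_b or {})
    if osm_ref is None:
        osm_ref = float(np.median(testing.data["osmolality"].to_numpy(float)))

    df = testing.data
    lnU = np.log(df["ufr"].to_numpy(float))
    reports: list[CorrelationReport] = []
    rankings: dict = {}
    for analyte in analytes:
        methods = ["unadjusted", "creatinine", "osmolality", "er", "erbw", "ufra"]
        if analyte in b_b and analyte in _BLOOD_COLUMN:
            methods.append("ufrb")
        series = {m: _ln_adjusted(testing, m, analyte, b_a, b_b, osm_ref,
                                  nondetect_policy) for m in methods}

        for crit, third in (("A", lnU),
                            ("B", np.log(df[_BLOOD_COLUMN[analyte]].to_numpy(float))
                             if analyte in _BLOOD_COLUMN else None)):
            if third is None:
                continue
            crit_reports = []
            for m in methods:
                rep = ln_pearson(np.exp(series[m]), np.exp(third))
                rep.method, rep.analyte, rep.criterion = m, analyte, crit
                crit_reports.append(rep)
            mat = np.eye(len(methods))
            for i in range(len(methods)):
                for j in range(i + 1, len(methods)):
                    rij = float(np.corrcoef(series[methods[i]],
                                            series[methods[j]])[0, 1])
                    mat[i, j] = mat[j, i] = max(-1.0, min(1.0, rij))
            letter_groups(crit_reports, mat, alpha=alpha)
            key = lambda rep: abs(rep.r_p) if crit == "A" else -rep.r_p
            rankings[(analyte, crit)] = [rep.method for rep in
                                         sorted(crit_reports, key=key)]
            reports.extend(crit_reports)
    return reports, rankings


def reports_to_frame(reports: list[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame([{"analyte": r.analyte, "criterion": r.criterion,
                          "method": r.method, "r": r.r_p, "ci_low": r.ci_low,
                          "ci_high": r.ci_high, "p": r.p_value, "n": r.n,
                          "letters": r.letter_group} for r in reports])


def gm_table(cohort: Cohort, b_table_a=None, b_table_b=None, osm_ref=None,
             analytes=DEFAULT_ANALYTES, nondetect_policy="as-is") -> pd.DataFrame:
    """Geometric means and ranges of adjusted concentrations per method."""
    rows = []
    b_a = dict(zip(b_table_a["analyte"], b_table_a["b_opt"])) \
        if isinstance(b_table_a, pd.DataFrame) else dict(b_table_a or {})
    methods = ["unadjusted", "creatinine", "osmolality", "er", "erbw"]
    for method in methods:
        kw = {"osm_ref": osm_ref} if method == "osmolality" else {}
        long = adjust_cohort(cohort, method, analytes=analytes,
                             nondetect_policy=nondetect_policy, **kw)
        for analyte, grp in long.groupby("analyte"):
            gm, (lo, hi) = geometric_mean(grp["value"])
            rows.append({"method": method, "analyte": analyte, "gm": gm,
                         "min": lo, "max": hi, "units": grp["units"].iloc[0]})
    if b_a:
        long = adjust_cohort(cohort, "ufr_power", b=b_a,
                             analytes=[a for a in analytes if a in b_a],
                             nondetect_policy=nondetect_policy)
        for analyte, grp in long.groupby("analyte"):
            gm, (lo, hi) = geometric_mean(grp["value"])
            rows.append({"method": "ufra", "analyte": analyte, "gm": gm,
                         "min": lo, "max": hi, "units": grp["units"].iloc[0]})
    return pd.DataFrame(rows)
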