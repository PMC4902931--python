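"""Empirical derivation of the analyte-specific flow-rate exponent (Araki's b).

The adjusted concentration on the natural-log scale is exactly

    ln(C · UFR^b) = ln C + b · ln UFR,

so the Pearson correlation of the adjusted value with any third variable is
an explicit function of b and five sample moments, and the whole 0–1.5 grid
is evaluated from those moments at once.  Two optimisation criteria are
supported:

* criterion A — minimise |r| of the adjusted concentration against ln UFR
  (hydration removal); its population optimum is the ordinary
  least-squares slope −cov(lnC, lnU)/var(lnU), which this module also
  exposes as an analytic cross-check;
* criterion B — maximise the signed r of the adjusted concentration against
  the ln blood concentration of the same analyte (internal-dose tracking).

r(b) against ln UFR is non-decreasing in b (strictly increasing while the
adjusted series is not collinear with ln UFR), so criterion A has a single
sign change and the grid optimum is the grid point nearest the analytic
root.  Ties break to the smallest b; when the adjusted series is exactly
constant the correlation is defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import analyte_concentration, ufr_power_adjust, DEFAULT_ANALYTES
from .cohort import Cohort

__all__ = ["BProfile", "make_grid", "profile_b", "closed_form_b_criterionA",
           "derive_b_table", "derive_subgroup_b", "apply_b", "DEFAULT_GRID",
           "SplitLeakageError", "AGE_BANDS", "assign_subgroups"]

#: (lo, hi, step) of the exponent grid: {0.00, 0.01, ..., 1.50}, 151 points.
DEFAULT_GRID = (0.0, 1.5, 0.01)

#: Age bands used for demographic sub-group derivation, (lo, hi) inclusive;
#: the final band is open-ended ("> 60").
AGE_BANDS = ((6, 11), (12, 19), (20, 39), (40, 59), (60, None))

_BLOOD_COLUMN = {"pb": "blood_pb", "cd": "blood_cd"}


class SplitLeakageError(RuntimeError):
    """Raised when b derivation is attempted on a testing split."""


@dataclass
class BProfile:
    """Grid of candidate exponents with the criterion correlation at each."""

    analyte: str | None
    criterion: str
    grid: np.ndarray
    r_at_b: np.ndarray
    b_opt: float
    r_opt: float
    n: int
    subgroup: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"analyte": self.analyte, "subgroup": self.subgroup,
                             "criterion": self.criterion, "b": self.grid,
                             "r": self.r_at_b})


def make_grid(lo=DEFAULT_GRID[0], hi=DEFAULT_GRID[1], step=DEFAULT_GRID[2]) -> np.ndarray:
    """Inclusive, constant-step exponent grid."""
    if step <= 0 or hi <= lo:
        raise ValueError("grid requires step > 0 and hi > lo")
    npts = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(npts)


def _validated(v, name, n_expected=None):
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if n_expected is not None and len(arr) != n_expected:
        raise ValueError(f"{name} must have length {n_expected}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.var(arr) == 0:
        raise ValueError(f"{name} has zero variance")
    return arr


def profile_b(lnC, lnU, target=None, criterion="A", grid=None,
              analyte=None, subgroup=None) -> BProfile:
    """Evaluate the criterion correlation over the exponent grid.

    Criterion "A" computes r(lnC + b·lnU, lnU) per grid b and minimises |r|;
    criterion "B" computes r(lnC + b·lnU, target) and maximises signed r
    (``target`` must be the ln blood concentrations).  Ties break to the
    smallest b; exact cancellation (constant adjusted series) counts as r=0.
    """
    if criterion not in ("A", "B"):
        raise ValueError("criterion must be 'A' or 'B'")
    lnC = _validated(lnC, "lnC")
    n = len(lnC)
    if n < 4:
        raise ValueError("need at least 4 observations")
    lnU = _validated(lnU, "lnU", n)
    if criterion == "B":
        if target is None:
            raise ValueError("criterion B requires target (ln blood concentrations)")
        third = _validated(target, "target", n)
    else:
        third = lnU
    grid = make_grid(*grid) if isinstance(grid, tuple) else \
        (make_grid() if grid is None else np.asarray(grid, dtype=float))

    # moments (population normalisation; correlations are ddof-invariant)
    c = lnC - lnC.mean()
    u = lnU - lnU.mean()
    w = third - third.mean()
    v_c, v_u, v_w = (c @ c) / n, (u @ u) / n, (w @ w) / n
    c_cu, c_cw, c_uw = (c @ u) / n, (c @ w) / n, (u @ w) / n

    var_adj = v_c + 2.0 * grid * c_cu + grid ** 2 * v_u
    var_adj = np.clip(var_adj, 0.0, None)
    cov_adj = c_cw + grid * c_uw
    scale = max(v_c, v_u) * 1e-15
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov_adj / np.sqrt(var_adj * v_w)
    r = np.where(var_adj <= scale, 0.0, r)   # exact-cancellation convention
    r = np.clip(r, -1.0, 1.0)

    if criterion == "A":
        i_opt = int(np.argmin(np.abs(r)))    # first minimum → smallest b
    else:
        i_opt = int(np.argmax(r))
    return BProfile(analyte=analyte, criterion=criterion, grid=grid, r_at_b=r,
                    b_opt=float(grid[i_opt]), r_opt=float(r[i_opt]), n=n,
                    subgroup=subgroup)


def closed_form_b_criterionA(lnC, lnU):
    """Analytic criterion-A optimum: −cov(lnC, lnU)/var(lnU) (the OLS slope
    of ln concentration on ln UFR, negated)."""
    lnC = _validated(lnC, "lnC")
    lnU = _validated(lnU, "lnU", len(lnC))
    u = lnU - lnU.mean()
    return float(-((lnC - lnC.mean()) @ u) / (u @ u))


def _guard_split(cohort, allow_testing):
    if isinstance(cohort, Cohort) and not allow_testing \
            and cohort.provenance.get("split") == "testing":
        raise SplitLeakageError(
            "refusing to derive b on a cohort tagged as the testing split; "
            "pass allow_testing=True to override")


def _ln_inputs(data, analyte, nondetect_policy):
    df = data.data if isinstance(data, Cohort) else data
    lnC = np.log(analyte_concentration(df, analyte, nondetect_policy))
    lnU = np.log(df["ufr"].to_numpy(float))
    return df, lnC, lnU


def derive_b_table(cohort, criterion="A", analytes=DEFAULT_ANALYTES, grid=None,
                   nondetect_policy="as-is", allow_testing=False
                   ) -> tuple[pd.DataFrame, list[BProfile]]:
    """Grid-derive one b per analyte on a (training) cohort.

    Criterion B is only available for analytes with a paired blood
    measurement (Pb, Cd); others are skipped with a warning.
    Returns (table, profiles); the table has columns analyte, subgroup,
    criterion, b_opt, r_opt, n and carries a provenance split tag in
    ``table.attrs``.
    """
    _guard_split(cohort, allow_testing)
    profiles = []
    for analyte in analytes:
        df, lnC, lnU = _ln_inputs(cohort, analyte, nondetect_policy)
        if criterion == "B":
            col = _BLOOD_COLUMN.get(analyte)
            if col is None:
                warnings.warn(f"criterion B unavailable for {analyte!r} "
                              "(no blood measurement); skipped", stacklevel=2)
                continue
            target = np.log(df[col].to_numpy(float))
        else:
            target = None
        profiles.append(profile_b(lnC, lnU, target=target, criterion=criterion,
                                  grid=grid, analyte=analyte))
    table = pd.DataFrame([{"analyte": p.analyte, "subgroup": p.subgroup,
                           "criterion": p.criterion, "b_opt": p.b_opt,
                           "r_opt": p.r_opt, "n": p.n} for p in profiles])
    if isinstance(cohort, Cohort):
        table.attrs["split"] = cohort.provenance.get("split")
    return table, profiles


def assign_subgroups(df: pd.DataFrame, grouping: str, age_bands=AGE_BANDS) -> pd.Series:
    """Label each record with its demographic subgroup."""
    if grouping == "gender_ethnicity":
        return df["ethnicity"].astype(str) + " " + df["gender"].astype(str)
    if grouping == "age_band":
        age = df["age"].to_numpy(float)
        labels = np.full(len(df), "", dtype=object)
        for lo, hi in age_bands:
            if hi is None:
                mask = age > lo
                name = f">{lo}"
            else:
                mask = (age >= lo) & (age < hi + 1)
                name = f"{lo}-{hi}"
            labels[mask] = name
        return pd.Series(labels, index=df.index)
    raise ValueError(f"unknown grouping: {grouping!r}")


def derive_subgroup_b(cohort, grouping, criterion="A", analytes=DEFAULT_ANALYTES,
                      grid=None, age_bands=AGE_BANDS, min_n=4,
                      nondetect_policy="as-is", allow_testing=False
                      ) -> pd.DataFrame:
    """Derive b per demographic subgroup × analyte.

    Also reports the two-sided p-value of the ln-concentration vs ln-UFR
    regression slope within each subgroup (criterion A's analytic anchor),
    so under-powered groups are visible.  Subgroups below ``min_n`` records
    are skipped with a warning, not an error.
    """
    _guard_split(cohort, allow_testing)
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    labels = assign_subgroups(df, grouping, age_bands)
    rows = []
    for name, sub in df.groupby(labels, sort=True):
        if name == "" or len(sub) < min_n:
            warnings.warn(f"subgroup {name!r} has n={len(sub)} < {min_n}; skipped",
                          stacklevel=2)
            continue
        for analyte in analytes:
            _, lnC, lnU = _ln_inputs(sub, analyte, nondetect_policy)
            if criterion == "B":
                col = _BLOOD_COLUMN.get(analyte)
                if col is None:
                    continue
                target = np.log(sub[col].to_numpy(float))
            else:
                target = None
            prof = profile_b(lnC, lnU, target=target, criterion=criterion,
                             grid=grid, analyte=analyte, subgroup=str(name))
            slope = stats.linregress(lnU, lnC)
            rows.append({"analyte": analyte, "subgroup": str(name),
                         "criterion": criterion, "b_opt": prof.b_opt,
                         "r_opt": prof.r_opt, "n": prof.n,
                         "slope": slope.slope, "slope_p": slope.pvalue})
    out = pd.DataFrame(rows, columns=["analyte", "subgroup", "criterion",
                                      "b_opt", "r_opt", "n", "slope", "slope_p"])
    if isinstance(cohort, Cohort):
        out.attrs["split"] = cohort.provenance.get("split")
    return out


def apply_b(cohort, b_table, mode="global", grouping=None, age_bands=AGE_BANDS,
            nondetect_policy="as-is") -> pd.DataFrame:
    """Apply the flow-rate power adjustment with a derived b table.

    ``b_table`` is the output of :func:`derive_b_table` (mode "global") or
    :func:`derive_subgroup_b` (mode "per_subgroup", with ``grouping``).
    Returns long-format results: sqn, analyte, method, value, units, b_used.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    tab = b_table if isinstance(b_table, pd.DataFrame) else pd.DataFrame(b_table)
    frames = []
    if mode == "global":
        lookup = dict(zip(tab["analyte"], tab["b_opt"]))
        for analyte in tab["analyte"].unique():
            c = analyte_concentration(df, analyte, nondetect_policy)
            val = ufr_power_adjust(c, df["ufr"].to_numpy(float), lookup[analyte])
            frames.append(pd.DataFrame({
                "sqn": df["sqn"].to_numpy(), "analyte": analyte,
                "method": "ufr_power", "value": np.asarray(val, dtype=float),
                "units": "ug/L at UFR 1 mL/min", "b_used": lookup[analyte]}))
    elif mode == "per_subgroup":
        if grouping is None:
            raise ValueError("per_subgroup mode requires grouping")
        labels = assign_subgroups(df, grouping, age_bands)
        lookup = {(r.analyte, r.subgroup): r.b_opt for r in tab.itertuples()}
        for analyte in tab["analyte"].unique():
            c = analyte_concentration(df, analyte, nondetect_policy)
            ufr = df["ufr"].to_numpy(float)
            b_vec = np.empty(len(df))
            for i, lab in enumerate(labels):
                key = (analyte, str(lab))
                if key not in lookup:
                    raise KeyError(f"no b value for subgroup {lab!r} (analyte {analyte!r})")
                b_vec[i] = lookup[key]
            val = ufr_power_adjust(c, ufr, b_vec)
            frames.append(pd.DataFrame({
                "sqn": df["sqn"].to_numpy(), "analyte": analyte,
                "method": "ufr_power", "value": np.asarray(val, dtype=float),
                "units": "ug/L at UFR 1 mL/min", "b_used": b_vec}))
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return pd.concat(frames, ignore_index=True)
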