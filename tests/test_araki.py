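"""Grid derivation of the flow-rate exponent and its analytic anchor."""

import dataclasses
import warnings

import numpy as np
import pytest

from urinadjust.araki import (DEFAULT_GRID, SplitLeakageError, apply_b,
                              closed_form_b_criterionA, derive_b_table,
                              derive_subgroup_b, make_grid, profile_b)
from urinadjust.synthetic import default_params, generate_cohort

from conftest import make_cohort, quiet_params


def _random_instance(rng, n, b_scale=1.0):
    lnU = rng.normal(0.0, rng.uniform(0.5, 1.5), n)
    b = rng.uniform(-0.2, 1.7) * b_scale
    lnC = 1.0 + rng.normal(0, rng.uniform(0.3, 1.2), n) - b * lnU
    return lnC, lnU


class TestGrid:
    def test_grid_is_151_points_with_exact_step(self):
        grid = make_grid()
        assert len(grid) == 151
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(1.5, abs=1e-12)
        steps = np.diff(grid)
        assert np.all(np.abs(steps - 0.01) < 1e-12)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            make_grid(0.0, 1.5, 0.0)


class TestProfileB:
    def test_noiseless_inversion_with_degenerate_convention(self):
        lnU = np.linspace(-1, 1, 50)
        prof = profile_b(-0.4 * lnU, lnU, criterion="A")
        assert prof.b_opt == pytest.approx(0.40)
        assert prof.r_opt == 0.0  # constant adjusted series => r defined as 0

    def test_exact_zero_covariance_gives_b_zero(self):
        lnU = np.array([-1.0, 1.0, -1.0, 1.0])
        lnC = np.array([-1.0, -1.0, 1.0, 1.0])  # orthogonal to lnU
        prof = profile_b(lnC, lnU, criterion="A")
        assert prof.b_opt == 0.0

    def test_grid_matches_closed_form_within_half_step(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            lnC, lnU = _random_instance(rng, 500)
            b_cf = closed_form_b_criterionA(lnC, lnU)
            prof = profile_b(lnC, lnU, criterion="A")
            if 0.0 <= b_cf <= 1.5:
                assert abs(prof.b_opt - b_cf) <= 0.005 + 1e-12
            else:
                assert prof.b_opt in (0.0, 1.5)

    def test_criterion_a_correlation_monotone_in_b(self):
        rng = np.random.default_rng(29)
        for _ in range(300):
            lnC, lnU = _random_instance(rng, 60)
            prof = profile_b(lnC, lnU, criterion="A")
            nondegenerate = prof.r_at_b != 0.0
            assert np.all(np.diff(prof.r_at_b[nondegenerate]) > -1e-12)

    def test_criterion_a_local_optimality(self):
        rng = np.random.default_rng(31)
        lnC, lnU = _random_instance(rng, 300, b_scale=0.5)
        prof = profile_b(lnC, lnU, criterion="A")
        i = int(np.argmin(np.abs(prof.r_at_b)))
        if 0 < i < len(prof.grid) - 1:
            assert abs(prof.r_at_b[i]) <= abs(prof.r_at_b[i - 1])
            assert abs(prof.r_at_b[i]) <= abs(prof.r_at_b[i + 1])

    def test_criterion_b_maximises_signed_r(self):
        rng = np.random.default_rng(37)
        n = 2000
        lnU = rng.normal(0, 1, n)
        dose = rng.normal(0, 1, n)
        lnC = dose - 0.6 * lnU + rng.normal(0, 0.2, n)
        blood = 0.9 * dose + rng.normal(0, 0.4, n)
        prof = profile_b(lnC, lnU, target=blood, criterion="B")
        # signed-r optimum sits at the generative exponent
        assert abs(prof.b_opt - 0.6) < 0.05
        assert prof.r_opt == np.max(prof.r_at_b)

    def test_guards(self):
        lnU = np.linspace(-1, 1, 10)
        with pytest.raises(ValueError, match="zero variance"):
            profile_b(np.zeros(10), lnU)
        with pytest.raises(ValueError, match="at least 4"):
            profile_b(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        with pytest.raises(ValueError, match="target"):
            profile_b(lnU * 2 + np.sin(lnU), lnU, criterion="B")


class TestClosedForm:
    def test_exact_slope(self):
        lnU = np.linspace(-2, 2, 30)
        assert closed_form_b_criterionA(3.0 - 0.52 * lnU + np.sin(lnU) * 0,
                                        lnU) == pytest.approx(0.52, abs=1e-12)

    def test_constant_lnc_rejected(self):
        with pytest.raises(ValueError):
            closed_form_b_criterionA(np.ones(10), np.linspace(-1, 1, 10))


class TestCohortDerivation:
    def test_recovers_generator_b_near_closed_form(self):
        cohort = generate_cohort(quiet_params(n=1723, seed=41))
        table, _ = derive_b_table(cohort, criterion="A")
        df = cohort.data
        lnU = np.log(df["ufr"].to_numpy())
        b_cf = closed_form_b_criterionA(np.log(df["urine_pb"].to_numpy()), lnU)
        b_grid = float(table.loc[table["analyte"] == "pb", "b_opt"].iloc[0])
        assert abs(b_grid - np.clip(b_cf, 0.0, 1.5)) <= 0.005 + 1e-12

    def test_dose_ufr_coupling_attenuates_criterion_a_not_b(self):
        """When the latent internal dose co-varies with hydration (the
        pooled-data pathology), the hydration-removal optimum is pulled away
        from the generative exponent while the blood-tracking optimum stays
        close to it."""
        params = quiet_params(n=20_000, seed=67)
        analytes = dict(params.analytes)
        analytes["pb"] = dataclasses.replace(analytes["pb"], dose_ufr_corr=0.3)
        cohort = generate_cohort(dataclasses.replace(params, analytes=analytes))
        ta, _ = derive_b_table(cohort, criterion="A", analytes=("pb",))
        tb, _ = derive_b_table(cohort, criterion="B", analytes=("pb",))
        b_a = float(ta["b_opt"].iloc[0])
        b_b = float(tb["b_opt"].iloc[0])
        # population value under criterion A: b_true - rho * sigma_dose / sigma_U
        assert b_a == pytest.approx(0.38 - 0.3 * 0.9, abs=0.03)
        assert abs(b_b - 0.38) < abs(b_a - 0.38)

    def test_leakage_guard_refuses_testing_split(self):
        cohort = generate_cohort(quiet_params(n=200, seed=43))
        testing = cohort.subset(cohort.sqns, {"split": "testing"})
        with pytest.raises(SplitLeakageError):
            derive_b_table(testing)
        table, _ = derive_b_table(testing, allow_testing=True)
        assert len(table) == 4


class TestSubgroups:
    def test_small_subgroups_skipped_with_warning(self):
        cohort = make_cohort([
            {"age": a, "ufr": u, "void_volume": u * 150.0}
            for a, u in zip([8, 15, 25, 50, 70], [0.3, 0.5, 0.7, 0.9, 1.2])])
        with pytest.warns(UserWarning, match="skipped"):
            table = derive_subgroup_b(cohort, "age_band")
        assert table.empty

    def test_homogeneous_b_spread_shrinks_with_n(self):
        spreads = []
        for n, seed in ((400, 47), (6400, 47)):
            cohort = generate_cohort(quiet_params(n=n, seed=seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = derive_subgroup_b(cohort, "gender_ethnicity",
                                          analytes=("pb",))
            spreads.append(table["b_opt"].max() - table["b_opt"].min())
        assert spreads[1] < spreads[0]

    def test_age_varying_exponent_recovered_monotone(self):
        """When the dilution exponent rises with age band, the per-band
        derivation recovers a monotone sequence (noiseless construction)."""
        rng = np.random.default_rng(73)
        band_ages = [8.0, 15.0, 25.0, 50.0, 70.0]
        band_b = [0.20, 0.30, 0.40, 0.50, 0.60]
        overrides = []
        for age, b in zip(band_ages, band_b):
            for _ in range(30):
                u = float(rng.lognormal(-0.36, 1.0))
                overrides.append({"age": age, "ufr": u,
                                  "void_volume": u * 150.0,
                                  "urine_pb": float(np.exp(0.5 - b * np.log(u)))})
        cohort = make_cohort(overrides)
        table = derive_subgroup_b(cohort, "age_band", analytes=("pb",))
        got = table.set_index("subgroup").loc[
            ["6-11", "12-19", "20-39", "40-59", ">60"], "b_opt"].to_numpy()
        np.testing.assert_allclose(got, band_b, atol=1e-9)

    def test_reports_slope_significance(self):
        cohort = generate_cohort(quiet_params(n=2000, seed=53))
        table = derive_subgroup_b(cohort, "age_band", analytes=("pb",))
        assert {"slope", "slope_p"} <= set(table.columns)
        assert (table["slope_p"] < 0.001).all()  # large groups, real slope


class TestApplyB:
    def test_global_b_zero_is_identity(self, tiny_cohort):
        import pandas as pd
        tab = pd.DataFrame({"analyte": ["pb"], "b_opt": [0.0]})
        out = apply_b(tiny_cohort, tab, mode="global")
        np.testing.assert_array_equal(out["value"].to_numpy(),
                                      tiny_cohort.data["urine_pb"].to_numpy())

    def test_uniform_subgroup_b_equals_global(self):
        cohort = generate_cohort(quiet_params(n=300, seed=59))
        import pandas as pd
        groups = sorted(set(cohort.data["ethnicity"] + " " + cohort.data["gender"]))
        tab_sub = pd.DataFrame({"analyte": "pb", "subgroup": groups, "b_opt": 0.4})
        tab_glob = pd.DataFrame({"analyte": ["pb"], "b_opt": [0.4]})
        a = apply_b(cohort, tab_sub, mode="per_subgroup", grouping="gender_ethnicity")
        b = apply_b(cohort, tab_glob, mode="global")
        np.testing.assert_allclose(a["value"].to_numpy(), b["value"].to_numpy(),
                                   rtol=1e-14)

    def test_missing_subgroup_b_named(self):
        cohort = generate_cohort(quiet_params(n=100, seed=61))
        import pandas as pd
        tab = pd.DataFrame({"analyte": ["pb"], "subgroup": ["6-11"],
                            "b_opt": [0.4]})
        with pytest.raises(KeyError):
            apply_b(cohort, tab, mode="per_subgroup", grouping="age_band")
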