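"""Assessment battery: partitioning, ln-scale inference, dependent
correlations, compact letter display and method scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from urinadjust.araki import SplitLeakageError, derive_b_table
from urinadjust.assess import (CorrelationReport, compact_letter_display,
                               evaluate_methods, geometric_mean, letter_groups,
                               ln_pearson, split_cohort, williams_test)
from urinadjust.synthetic import generate_cohort

from conftest import quiet_params


class TestSplit:
    def test_sizes_and_determinism(self):
        cohort = generate_cohort(quiet_params(n=10, seed=1))
        sp = split_cohort(cohort, fraction=0.8, seed=7)
        assert len(sp.training_sqns) == 8 and len(sp.testing_sqns) == 2
        sp2 = split_cohort(cohort, fraction=0.8, seed=7)
        assert np.array_equal(sp.training_sqns, sp2.training_sqns)
        assert not set(sp.training_sqns) & set(sp.testing_sqns)

    def test_round_half_even_at_2151(self):
        cohort = generate_cohort(quiet_params(n=2151, seed=2))
        sp = split_cohort(cohort, fraction=0.8, seed=0)
        # 0.8 * 2151 = 1720.8 -> 1721 under round-half-even
        assert len(sp.training_sqns) == 1721
        assert len(sp.testing_sqns) == 430

    def test_stratified_split_preserves_groups(self):
        cohort = generate_cohort(quiet_params(n=1000, seed=3))
        sp = split_cohort(cohort, fraction=0.8, seed=0, stratify_by="gender")
        train, test = sp.apply(cohort)
        for g, grp in cohort.data.groupby("gender"):
            frac = (train.data["gender"] == g).sum() / len(grp)
            assert abs(frac - 0.8) < 0.01

    def test_too_small_rejected(self):
        cohort = generate_cohort(quiet_params(n=4, seed=4))
        with pytest.raises(ValueError):
            split_cohort(cohort, fraction=0.9, seed=0)

    def test_split_tags_provenance(self):
        cohort = generate_cohort(quiet_params(n=20, seed=5))
        train, test = split_cohort(cohort, seed=0).apply(cohort)
        assert train.provenance["split"] == "training"
        assert test.provenance["split"] == "testing"


class TestGeometricMean:
    def test_examples(self):
        gm, (lo, hi) = geometric_mean([1.0, 10.0, 100.0])
        assert gm == pytest.approx(10.0)
        assert (lo, hi) == (1.0, 100.0)
        gm, _ = geometric_mean(np.full(7, 3.3))
        assert gm == pytest.approx(3.3)

    def test_scale_property(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0, 1, 100)
        assert geometric_mean(5.0 * x)[0] == pytest.approx(
            5.0 * geometric_mean(x)[0], rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean([1.0, 0.0])


class TestLnPearson:
    def test_perfect_correlations(self):
        x = np.exp(np.linspace(-1, 1, 20))
        assert ln_pearson(x, x).r_p == 1.0
        rep = ln_pearson(x, 1.0 / x)
        assert rep.r_p == -1.0 and rep.degenerate

    def test_ci_coverage_monte_carlo(self):
        """Fisher-z 95% CI covers the true ln-scale correlation ~95% of
        the time for bivariate lognormal data at n=428."""
        rng = np.random.default_rng(8)
        rho, n, nsim = 0.5, 428, 500
        cov = np.array([[1.0, rho], [rho, 1.0]])
        L = np.linalg.cholesky(cov)
        hits = 0
        for _ in range(nsim):
            z = rng.standard_normal((n, 2)) @ L.T
            rep = ln_pearson(np.exp(z[:, 0]), np.exp(z[:, 1]))
            hits += rep.ci_low <= rho <= rep.ci_high
        assert abs(hits / nsim - 0.95) < 0.025

    def test_unit_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(0, 1, 50)
        y = rng.lognormal(0, 1, 50)
        assert ln_pearson(x, y).r_p == pytest.approx(
            ln_pearson(10.0 * x, 0.1 * y).r_p, abs=1e-14)


class TestWilliams:
    def test_equal_correlations_give_t_zero_p_one(self):
        res = williams_test(0.4, 0.4, 0.2, 100)
        assert res.t_statistic == 0.0 and res.p_value == 1.0
        assert res.df == 97

    def test_antisymmetry(self):
        a = williams_test(0.6, 0.3, 0.4, 80)
        b = williams_test(0.3, 0.6, 0.4, 80)
        assert a.t_statistic == pytest.approx(-b.t_statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_guards(self):
        with pytest.raises(ValueError):
            williams_test(0.5, 0.5, 0.3, 3)
        with pytest.raises(ValueError):
            williams_test(1.0, 0.5, 0.3, 100)
        with pytest.raises(ValueError, match="semidefinite"):
            williams_test(0.9, -0.9, 0.9, 100)


class TestLetterDisplay:
    @staticmethod
    def _valid(letters, sig, m):
        for i, j in itertools.combinations(range(m), 2):
            share = any(i in L and j in L for L in letters)
            if sig[i][j]:
                assert not share, (i, j)
            else:
                assert share, (i, j)

    def test_random_patterns_valid(self):
        rng = np.random.default_rng(10)
        for m in range(2, 7):
            for _ in range(60):
                sig = np.zeros((m, m), dtype=bool)
                iu = np.triu_indices(m, 1)
                vals = rng.random(len(iu[0])) < 0.4
                sig[iu] = vals
                sig |= sig.T
                letters = compact_letter_display(m, lambda i, j: sig[i][j])
                self._valid(letters, sig, m)

    def test_chain_pattern(self):
        """A~B, B~C but A and C differ: letters a / ab / b."""
        sig = [[False, False, True], [False, False, False], [True, False, False]]
        letters = compact_letter_display(3, lambda i, j: sig[i][j])
        assert sorted(map(sorted, letters)) == [[0, 1], [1, 2]]

    def test_letter_groups_end_to_end(self):
        n = 428
        reports = [CorrelationReport(m, "pb", "B", r, r, r, 0.0, n)
                   for m, r in [("m1", 0.80), ("m2", 0.79), ("m3", 0.50)]]
        between = np.array([[1.0, 0.95, 0.6], [0.95, 1.0, 0.6], [0.6, 0.6, 1.0]])
        letter_groups(reports, between)
        assert reports[0].letter_group == "a"       # best
        assert reports[1].letter_group == "a"       # indistinguishable from m1
        assert reports[2].letter_group == "b"       # clearly weaker

    def test_all_same_and_all_distinct(self):
        letters = compact_letter_display(4, lambda i, j: False)
        assert letters == [set(range(4))]
        letters = compact_letter_display(4, lambda i, j: True)
        assert sorted(map(sorted, letters)) == [[0], [1], [2], [3]]

    def test_mismatched_n_rejected(self):
        reports = [CorrelationReport("a", "pb", "B", 0.5, 0, 1, 0.0, 100),
                   CorrelationReport("b", "pb", "B", 0.4, 0, 1, 0.0, 99)]
        with pytest.raises(ValueError, match="same n"):
            letter_groups(reports, np.eye(2))


@pytest.fixture(scope="module")
def fitted():
    cohort = generate_cohort(quiet_params(n=2151, seed=12))
    train, test = split_cohort(cohort, seed=0).apply(cohort)
    table_a, _ = derive_b_table(train, criterion="A")
    table_b, _ = derive_b_table(train, criterion="B", analytes=("pb", "cd"))
    osm_ref = float(np.median(train.data["osmolality"]))
    return train, test, table_a, table_b, osm_ref


class TestEvaluateMethods:
    def test_qualitative_sign_pattern(self, fitted):
        """Unadjusted correlates negatively with UFR, ER positively, and the
        criterion-A-tuned adjustment beats both on the held-out split (its
        residual correlation there is sampling noise, not exactly zero)."""
        _, test, table_a, table_b, osm_ref = fitted
        reports, _ = evaluate_methods(test, table_a, table_b, osm_ref=osm_ref)
        frame = {(r.analyte, r.criterion, r.method): r for r in reports}
        for analyte in ("pb", "cd", "as_imm", "i"):
            assert frame[(analyte, "A", "unadjusted")].r_p < 0
            assert frame[(analyte, "A", "er")].r_p > 0
            assert abs(frame[(analyte, "A", "ufra")].r_p) < \
                abs(frame[(analyte, "A", "unadjusted")].r_p)
            assert abs(frame[(analyte, "A", "ufra")].r_p) < \
                abs(frame[(analyte, "A", "er")].r_p)

    def test_training_self_consistency(self, fitted):
        """Evaluating the criterion-A exponent on its own training split
        leaves only the grid-resolution residual."""
        train, _, table_a, table_b, osm_ref = fitted
        reports, _ = evaluate_methods(
            train.subset(train.sqns, {"split": "training"}),
            table_a, table_b, osm_ref=osm_ref)
        for rep in reports:
            if rep.criterion == "A" and rep.method == "ufra":
                assert abs(rep.r_p) <= 0.01

    def test_b_zero_equals_unadjusted_bitwise(self, fitted):
        _, test, _, table_b, osm_ref = fitted
        zero = pd.DataFrame({"analyte": ["pb", "cd", "as_imm", "i"],
                             "b_opt": [0.0] * 4})
        reports, _ = evaluate_methods(test, zero, table_b, osm_ref=osm_ref)
        frame = {(r.analyte, r.criterion, r.method): r for r in reports}
        for analyte in ("pb", "cd", "as_imm", "i"):
            assert frame[(analyte, "A", "ufra")].r_p == \
                frame[(analyte, "A", "unadjusted")].r_p

    def test_creatinine_criterion_a_algebraic_identity(self, fitted):
        """r(ln creatinine-adjusted, ln UFR) equals the correlation of
        ln C − ln C_cr with ln UFR computed directly."""
        _, test, table_a, table_b, osm_ref = fitted
        reports, _ = evaluate_methods(test, table_a, table_b, osm_ref=osm_ref)
        rep = next(r for r in reports
                   if (r.analyte, r.criterion, r.method) == ("pb", "A", "creatinine"))
        df = test.data
        direct = np.corrcoef(np.log(df["urine_pb"]) - np.log(df["urine_creatinine"]),
                             np.log(df["ufr"]))[0, 1]
        assert rep.r_p == pytest.approx(direct, abs=1e-12)

    def test_testing_derived_b_refused(self, fitted):
        _, test, _, _, osm_ref = fitted
        leaky, _ = derive_b_table(test, allow_testing=True)
        assert leaky.attrs["split"] == "testing"
        with pytest.raises(SplitLeakageError):
            evaluate_methods(test, leaky, osm_ref=osm_ref)

    def test_ranking_invariant_to_unit_rescaling(self, fitted):
        _, test, table_a, table_b, osm_ref = fitted
        scaled = test.subset(test.sqns)
        scaled.data["urine_pb"] = scaled.data["urine_pb"] * 1000.0  # ng/L
        _, ranks_orig = evaluate_methods(test, table_a, table_b, osm_ref=osm_ref)
        _, ranks_scaled = evaluate_methods(scaled, table_a, table_b, osm_ref=osm_ref)
        assert ranks_orig[("pb", "A")] == ranks_scaled[("pb", "A")]
        assert ranks_orig[("pb", "B")] == ranks_scaled[("pb", "B")]
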