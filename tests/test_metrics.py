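"""2x2 tables, the seven-statistic battery, chi-square and sample size."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mnemoscreen as ms
from conftest import make_cohort

cells = st.integers(min_value=1, max_value=500)


class TestCrossTabulate:
    @pytest.mark.parametrize("symptom", ms.SYMPTOMS)
    def test_reference_counts(self, reference_cohort, symptom):
        t = ms.cross_tabulate(reference_cohort, symptom)
        assert (t.a, t.b, t.c, t.d) == ms.REFERENCE_SYMPTOM_TABLES[symptom]

    def test_degenerate_all_present_all_diseased(self):
        cohort = make_cohort(
            [{"chest_pain": True, "outcome": "ACS"} for _ in range(7)],
            ("chest_pain",),
        )
        t = ms.cross_tabulate(cohort, "chest_pain")
        assert (t.a, t.b, t.c, t.d) == (7, 0, 0, 0)

    def test_zero_evaluable_rows_rejected(self):
        cohort = make_cohort(
            [{"chest_pain": None, "outcome": "ACS"}], ("chest_pain",)
        )
        with pytest.raises(ValueError, match="evaluable"):
            ms.cross_tabulate(cohort, "chest_pain")

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ms.TwoByTwo(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            ms.TwoByTwo(0, 0, 0, 0)


class TestDiagnosticProfile:
    def test_chest_pain_battery_two_dp(self):
        p = ms.diagnostic_profile(ms.TwoByTwo(367, 1539, 34, 1055))
        assert round(p.sensitivity.point, 2) == 0.92
        assert round(p.specificity.point, 2) == 0.41
        assert round(p.npv.point, 2) == 0.97
        assert round(p.lr_pos.point, 2) == 1.54
        assert round(p.odds_ratio.point, 2) == 7.40

    def test_perfect_test(self):
        p = ms.diagnostic_profile(ms.TwoByTwo(5, 0, 0, 9))
        assert p.sensitivity.point == 1.0
        assert p.specificity.point == 1.0
        assert "haldane" in p.odds_ratio.method

    def test_lr_pos_by_direct_arithmetic(self):
        # sweating counts: LR+ = (132/312)/(1 - 1337/1657)
        p = ms.diagnostic_profile(ms.TwoByTwo(132, 320, 180, 1337))
        expected = (132 / 312) / (1 - 1337 / 1657)
        assert p.lr_pos.point == pytest.approx(expected, rel=1e-12)
        assert round(p.lr_pos.point, 2) == 2.19

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ms.diagnostic_profile(ms.TwoByTwo(3, 0, 4, 0))

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_bayes_consistency_of_ppv(self, a, b, c, d):
        """PPV equals Se*pi / (Se*pi + (1-Sp)(1-pi)) at the table prevalence."""
        p = ms.diagnostic_profile(ms.TwoByTwo(a, b, c, d))
        pi = (a + c) / (a + b + c + d)
        se, sp = p.sensitivity.point, p.specificity.point
        expected = se * pi / (se * pi + (1 - sp) * (1 - pi))
        assert p.ppv.point == pytest.approx(expected, abs=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ci_brackets_point(self, a, b, c, d):
        p = ms.diagnostic_profile(ms.TwoByTwo(a, b, c, d))
        for s in ms.STATISTICS:
            e = p.statistic(s)
            assert e.lower <= e.point <= e.upper

    def test_row_order_permutation_invariance(self, reference_cohort):
        rng = np.random.default_rng(4)
        shuffled = ms.CohortTable(
            reference_cohort.df.sample(frac=1, random_state=rng.integers(2**31)),
            reference_cohort.symptom_names,
        )
        for s in ("chest_pain", "syncope"):
            p0 = ms.diagnostic_profile(ms.cross_tabulate(reference_cohort, s))
            p1 = ms.diagnostic_profile(ms.cross_tabulate(shuffled, s))
            for stat in ms.STATISTICS:
                assert p0.statistic(stat).point == p1.statistic(stat).point


class TestOddsRatio:
    def test_cross_product_examples(self):
        assert round(ms.odds_ratio(ms.TwoByTwo(367, 1539, 34, 1055)).point, 2) == 7.40
        assert ms.odds_ratio(ms.TwoByTwo(1, 1, 1, 1)).point == 1.0
        assert round(ms.odds_ratio(ms.TwoByTwo(32, 347, 109, 708)).point, 2) == 0.60

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=30)
    def test_logistic_mle_equals_cross_product(self, a, b, c, d):
        t = ms.TwoByTwo(a, b, c, d)
        cp = ms.odds_ratio(t, estimator="cross_product").point
        mle = ms.odds_ratio(t, estimator="logistic_mle").point
        assert mle == pytest.approx(cp, rel=1e-9)


class TestChiSquare:
    def test_independence_gives_zero(self):
        stat, p = ms.chi_square_association(ms.TwoByTwo(10, 90, 20, 180))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_expected_count_oracle(self):
        t = ms.TwoByTwo(367, 1539, 34, 1055)
        obs = t.as_array()
        row, col = obs.sum(axis=1), obs.sum(axis=0)
        exp = np.outer(row, col) / obs.sum()
        oracle = float(((obs - exp) ** 2 / exp).sum())
        stat, p = ms.chi_square_association(t, correction="none")
        assert stat == pytest.approx(oracle, rel=1e-12)
        assert 0 < p < 1e-10  # strongly associated

    def test_yates_shrinks_statistic(self):
        t = ms.TwoByTwo(1, 0, 0, 1)
        plain, _ = ms.chi_square_association(t, correction="none")
        yates, _ = ms.chi_square_association(t, correction="yates")
        assert yates < plain

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            ms.chi_square_association(ms.TwoByTwo(2, 3, 0, 0))


class TestSampleSize:
    def test_reference_plan(self):
        plan = ms.sample_size_plan(0.5, 0.05, 0.05, prevalence=0.274, dropout=0.30)
        assert plan.n0 == 385
        assert plan.n_required == 2009

    def test_no_inflation(self):
        plan = ms.sample_size_plan(0.5, 0.05, 0.05, prevalence=1.0, dropout=0.0)
        assert plan.n_required == plan.n0 == 385

    def test_formula_oracle(self):
        z = stats.norm.ppf(0.975)
        expected = math.ceil(z * z * 0.274 * 0.726 / 0.05**2)
        plan = ms.sample_size_plan(0.274, 0.05, 0.05)
        assert plan.n0 == expected

    @pytest.mark.parametrize("kwargs", [
        dict(p=0.0, d=0.05), dict(p=0.5, d=1.5),
        dict(p=0.5, d=0.05, prevalence=0.0),
        dict(p=0.5, d=0.05, dropout=1.0),
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ms.sample_size_plan(**kwargs)


def test_wilson_coverage_sanity():
    """Wilson 95% CIs for sensitivity keep >=90% empirical coverage.

    Fixed Se=0.85 and 244 diseased of n=2,000 (prevalence 12.2%); 2,000
    simulated tables.
    """
    rng = np.random.default_rng(2024)
    se_true, n_dis = 0.85, 244
    k = rng.binomial(n_dis, se_true, size=2000)
    covered = 0
    for ki in k:
        p = ms.diagnostic_profile(ms.TwoByTwo(int(ki), 10, int(n_dis - ki), 10))
        if p.sensitivity.lower <= se_true <= p.sensitivity.upper:
            covered += 1
    assert covered / 2000 >= 0.90
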