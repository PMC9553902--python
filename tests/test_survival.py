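"""KM, log-rank and Cox against hand computations, naive re-implementations,
and lifelines as an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from spongescope.simulate import SurvivalSimSpec, simulate_survival_cohort
from spongescope.survival import (
    SurvivalCohort,
    cox_fit,
    cox_partial_loglik,
    km_estimate,
    logrank_test,
    median_split,
)


class TestKaplanMeier:
    def test_three_subject_worked_example(self):
        # events at 1 and 3, censored at 2: S = 2/3 after t=1, 0 after t=3
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.event_times.tolist() == [1.0, 3.0]
        assert km.survival == pytest.approx([2 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 1]
        assert km.median == 3.0

    def test_all_censored_is_flat_with_undefined_median(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100.0) == 1.0
        assert km.median is None

    def test_simultaneous_events_drop_to_zero_in_one_step(self):
        km = km_estimate([5.0] * 4, [1, 1, 1, 1])
        assert km.survival.tolist() == [0.0]
        assert km.at_risk.tolist() == [4]

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 200)
        km = km_estimate(t, np.ones(200, dtype=int))
        for tt, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(1 - np.mean(t <= tt))

    def test_matches_lifelines(self):
        rng = np.random.default_rng(1)
        t = rng.integers(1, 20, 100).astype(float)
        e = rng.integers(0, 2, 100)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tt, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(float(kmf.survival_function_at_times(tt).iloc[0]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [1, 1, 0, 1, 1]
        res = logrank_test(["a"] * 5 + ["b"] * 5, t + t, e + e)
        assert res.chi_square == 0.0
        assert res.p_value == 1.0

    def test_separated_groups_hand_computation(self):
        # A events at 1,2,3; B events at 4,5,6; no censoring.
        # Hypergeometric O-E and variance summed over the six event times.
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = ["A", "A", "A", "B", "B", "B"]
        o_minus_e, var = 0.0, 0.0
        at_risk = [(3, 3), (2, 3), (1, 3), (0, 3), (0, 2), (0, 1)]
        observed = [1, 1, 1, 0, 0, 0]
        for (nA, nB), oA in zip(at_risk, observed):
            n = nA + nB
            e = nA / n
            o_minus_e += oA - e
            if n > 1:
                var += (nA * nB * (n - 1)) / (n * n * (n - 1))  # d=1, so d(n-d)/(n-1)=1
        expected_chi2 = o_minus_e**2 / var
        res = logrank_test(labels, t, [1] * 6)
        assert res.chi_square == pytest.approx(expected_chi2)
        assert res.df == 1

    def test_matches_lifelines_with_ties_and_censoring(self):
        rng = np.random.default_rng(2)
        for k in (2, 3):
            t = rng.integers(1, 8, 120).astype(float)
            e = rng.integers(0, 2, 120)
            g = rng.integers(0, k, 120)
            mine = logrank_test(g, t, e)
            ref = multivariate_logrank_test(t, g, e)
            assert mine.chi_square == pytest.approx(ref.test_statistic)
            assert mine.p_value == pytest.approx(ref.p_value)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(3, 80)
        e = rng.integers(0, 2, 80)
        g = rng.integers(0, 2, 80)
        r1 = logrank_test(g, t, e)
        perm = rng.permutation(80)
        r2 = logrank_test(g[perm], t[perm], e[perm])
        assert r1.chi_square == pytest.approx(r2.chi_square)

    def test_two_group_statistic_is_squared_standardised_sum(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(3, 60)
        e = np.ones(60, dtype=int)
        g = rng.integers(0, 2, 60)
        res = logrank_test(g, t, e)
        # naive independent accumulation
        oe, v = 0.0, 0.0
        for tt in np.unique(t[e == 1]):
            risk = t >= tt
            n = risk.sum()
            n1 = (risk & (g == 0)).sum()
            d = ((t == tt) & (e == 1)).sum()
            d1 = ((t == tt) & (e == 1) & (g == 0)).sum()
            oe += d1 - d * n1 / n
            if n > 1:
                v += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
        assert res.chi_square == pytest.approx(oe**2 / v)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(["a", "a"], [1.0, 2.0], [1, 1])


class TestCox:
    def test_null_covariate_near_zero(self):
        cohort, _ = simulate_survival_cohort(
            SurvivalSimSpec(n_samples=500, n_genes=1, censoring_rate=0.0, rng_seed=6)
        )
        fit = cox_fit(cohort.expression.to_numpy(), cohort.time, cohort.event)
        assert fit.converged
        assert abs(fit.coefficients[0]) < 3 * fit.se[0]

    def test_toy_fit_matches_grid_search_of_partial_likelihood(self):
        rng = np.random.default_rng(7)
        n = 30
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x)))
        e = np.ones(n, dtype=int)
        fit = cox_fit(x, t, e)

        def naive_ll(beta):
            order = np.argsort(t)
            ll = 0.0
            for i in order:
                risk = t >= t[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.arange(-3, 3, 1e-3)
        lls = [naive_ll(b) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert abs(fit.coefficients[0] - beta_grid) <= 1e-3

    def test_recovers_planted_beta(self):
        cohort, _ = simulate_survival_cohort(
            SurvivalSimSpec(
                n_samples=500, n_genes=1, prognostic_genes={"S0001": 0.8},
                censoring_rate=0.0, rng_seed=9,
            )
        )
        fit = cox_fit(cohort.expression.to_numpy(), cohort.time, cohort.event)
        assert abs(fit.coefficients[0] - 0.8) < 0.15

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_lifelines(self, ties):
        rng = np.random.default_rng(10)
        n = 150
        X = rng.standard_normal((n, 3))
        t = rng.integers(1, 12, n).astype(float)  # heavy ties
        e = rng.integers(0, 2, n)
        fit = cox_fit(X, t, e, ties=ties)
        df = pd.DataFrame(X, columns=list("abc"))
        df["T"], df["E"] = t, e
        # lifelines fits with the Efron approximation
        cph = CoxPHFitter().fit(df, "T", "E")
        if ties == "efron":
            assert fit.coefficients == pytest.approx(cph.params_.values, abs=1e-5)
            assert fit.se == pytest.approx(cph.standard_errors_.values, abs=1e-5)
            assert fit.log_partial_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)
        else:
            assert fit.coefficients == pytest.approx(cph.params_.values, abs=0.05)

    def test_fixed_beta_loglik_matches_lifelines_at_its_optimum(self):
        cohort, _ = simulate_survival_cohort(
            SurvivalSimSpec(n_samples=200, n_genes=2, prognostic_genes={"S0001": 0.6}, rng_seed=11)
        )
        X = cohort.expression.to_numpy()
        df = cohort.expression.copy()
        df["T"], df["E"] = cohort.time, cohort.event
        cph = CoxPHFitter().fit(df, "T", "E")
        ll = cox_partial_loglik(X, cohort.time, cohort.event, cph.params_.values)
        assert ll == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_binary_covariate_matches_exponential_closed_form(self):
        cohort, _ = simulate_survival_cohort(
            SurvivalSimSpec(n_samples=2000, n_genes=1, censoring_rate=0.0, rng_seed=12)
        )
        g = (cohort.expression.iloc[:, 0].to_numpy() > 0).astype(float)
        # re-generate times with a true binary effect
        rng = np.random.default_rng(13)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.9 * g)))
        e = np.ones_like(g, dtype=int)
        fit = cox_fit(g, t, e)
        d1, T1 = e[g == 1].sum(), t[g == 1].sum()
        d0, T0 = e[g == 0].sum(), t[g == 0].sum()
        closed_form = (d1 / T1) / (d0 / T0)
        assert np.exp(fit.coefficients[0]) == pytest.approx(closed_form, rel=0.10)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant covariate"):
            cox_fit(np.ones(10), np.arange(1, 11, dtype=float), np.ones(10, dtype=int))

    def test_perfect_separation_flagged(self):
        # events only where x is large: monotone likelihood
        x = np.r_[np.zeros(20), np.ones(20)]
        t = np.r_[np.full(20, 10.0), np.linspace(1, 2, 20)]
        e = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        fit = cox_fit(x, t, e, max_iter=200)
        assert (not fit.converged) or abs(fit.coefficients[0]) > 5


class TestMedianSplit:
    def test_even_n(self):
        labels, degenerate = median_split([1.0, 2.0, 3.0, 4.0])
        assert labels.tolist() == ["low", "low", "high", "high"]
        assert not degenerate

    def test_odd_n_at_median_goes_low(self):
        labels, degenerate = median_split([1.0, 2.0, 3.0])
        assert labels.tolist() == ["low", "low", "high"]
        assert not degenerate

    def test_all_identical_is_degenerate(self):
        _, degenerate = median_split([5.0, 5.0, 5.0])
        assert degenerate

    def test_at_median_high_option(self):
        labels, _ = median_split([1.0, 2.0, 3.0], at_median="high")
        assert labels.tolist() == ["low", "high", "high"]


class TestCohortValidation:
    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SurvivalCohort(["a"], np.array([0.0]), np.array([1]), pd.DataFrame({"g": [1.0]}))

    def test_bad_event_rejected(self):
        with pytest.raises(ValueError, match="event"):
            SurvivalCohort(["a"], np.array([1.0]), np.array([2]), pd.DataFrame({"g": [1.0]}))
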