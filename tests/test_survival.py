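"""Top-quartile dichotomization, KM, log-rank and the Cox model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import driverseek as ds
from driverseek.errors import SurvivalError
from driverseek.survival import (
    cox_hr,
    dichotomize_top_quartile,
    km_estimator,
    logrank_test,
    survival_report,
)

from conftest import make_cohort


class TestDichotomize:
    def test_linear_interpolation_quantile(self):
        # values 1..8: Q3 = 6.25, so only 7 and 8 are high
        groups = dichotomize_top_quartile(pd.Series(range(1, 9)))
        assert list(groups) == ["low"] * 6 + ["high"] * 2

    def test_single_outlier(self):
        groups = dichotomize_top_quartile(pd.Series([1, 1, 1, 1, 1, 1, 1, 9]))
        assert list(groups).count("high") == 1

    def test_boundary_ties_are_low(self):
        # Q3 of [1..6, 6, 6] is exactly 6; strict > puts the tied 6s low
        groups = dichotomize_top_quartile(pd.Series([1, 2, 3, 4, 5, 6, 6, 6]))
        assert "high" not in set(groups)

    def test_constant_expression_is_error(self):
        with pytest.raises(SurvivalError, match="constant"):
            dichotomize_top_quartile(pd.Series([3.0] * 10))

    def test_small_sample_is_error(self):
        with pytest.raises(SurvivalError, match="8 samples"):
            dichotomize_top_quartile(pd.Series(range(5)))


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        sf = km_estimator([1, 2, 3], [1, 1, 1])
        assert sf.loc[1.0] == pytest.approx(2 / 3)
        assert sf.loc[2.0] == pytest.approx(1 / 3)
        assert sf.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        sf = km_estimator([1, 2, 3], [0, 0, 0])
        assert (sf == 1.0).all()

    def test_censoring_shrinks_risk_set(self):
        # times {1, 2+, 3}: S(1) = 2/3, S(3) = (2/3)*(0/1) = 0
        sf = km_estimator([1, 2, 3], [1, 0, 1])
        assert sf.loc[1.0] == pytest.approx(2 / 3)
        assert sf.loc[3.0] == pytest.approx(0.0)

    def test_starts_at_one_and_non_increasing(self):
        rng = np.random.default_rng(0)
        sf = km_estimator(rng.exponential(10, 50), rng.random(50) < 0.7)
        assert sf.iloc[0] == 1.0
        assert (np.diff(sf.to_numpy()) <= 1e-12).all()

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40)
        sf = km_estimator(t, np.ones(40, bool))
        for time, s in sf.items():
            assert s == pytest.approx((t > time).mean(), abs=1e-12)

    def test_negative_time_is_error(self):
        with pytest.raises(SurvivalError):
            km_estimator([-1, 2], [1, 1])


def _brute_logrank(ta, ea, tb, eb):
    """Independent O-E tabulation of the log-rank statistic."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O = E = V = 0.0
    for t in times:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        da = ((ta == t) & ea).sum()
        db = ((tb == t) & eb).sum()
        n, d = na + nb, da + db
        O += da
        E += d * na / n
        if n > 1:
            V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogRank:
    def test_identical_groups(self):
        chisq, p = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert chisq == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(10, 30), rng.exponential(20, 30)
        ea, eb = np.ones(30, bool), np.ones(30, bool)
        a = logrank_test(ta, ea, tb, eb)
        b = logrank_test(tb, eb, ta, ea)
        assert a == pytest.approx(b)

    def test_matches_brute_force_tabulation(self):
        ta, ea = [1, 2, 3], [1, 1, 1]
        tb, eb = [4, 5, 6], [1, 1, 1]
        chisq, _ = logrank_test(ta, ea, tb, eb)
        assert chisq == pytest.approx(_brute_logrank(ta, ea, tb, eb), rel=1e-9)

    def test_zero_events_is_error(self):
        with pytest.raises(SurvivalError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_null_p_values_uniform(self):
        """Under the null the log-rank p is uniform (KS over 200 replicates)."""
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(200):
            ta, tb = rng.exponential(30, 40), rng.exponential(30, 40)
            ca, cb = rng.uniform(0, 150, 40), rng.uniform(0, 150, 40)
            _, p = logrank_test(
                np.minimum(ta, ca), ta <= ca, np.minimum(tb, cb), tb <= cb
            )
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestCox:
    def test_identical_event_patterns_give_unit_hr(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 0, 1, 1, 1, 0]
        x = [1, 1, 1, 1, 0, 0, 0, 0]
        res = cox_hr(t, e, x)
        assert res.hr == pytest.approx(1.0, abs=1e-10)

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 60)
        e = rng.random(60) < 0.8
        x = (rng.random(60) < 0.5).astype(int)
        if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
            pytest.skip("degenerate draw")
        a = cox_hr(t, e, x)
        b = cox_hr(t, e, 1 - x)
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-8)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        t = np.concatenate([rng.exponential(10, 50), rng.exponential(20, 50)])
        e = rng.random(100) < 0.8
        x = np.r_[np.ones(50), np.zeros(50)]
        ours = cox_hr(t, e, x)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        theirs = float(np.exp(CoxPHFitter().fit(df, "t", "e").params_.iloc[0]))
        assert ours.hr == pytest.approx(theirs, rel=1e-6)

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(5)
        n = 200
        h0 = np.log(2) / 30
        t = np.concatenate([rng.exponential(1 / (2 * h0), n), rng.exponential(1 / h0, n)])
        c = rng.uniform(0, 150, 2 * n)
        x = np.r_[np.ones(n), np.zeros(n)]
        res = cox_hr(np.minimum(t, c), t <= c, x)
        assert 1.6 <= res.hr <= 2.5
        assert res.ci95[0] <= 2.0 <= res.ci95[1]

    def test_complete_separation_sentinel(self):
        # all high-group events strictly before any low-group event
        res = cox_hr([1, 2, 3, 10, 11, 12], [1, 1, 1, 1, 1, 1], [1, 1, 1, 0, 0, 0])
        assert not res.converged
        assert res.hr in (0.0, np.inf)

    def test_no_events_in_one_group_is_error(self):
        with pytest.raises(SurvivalError):
            cox_hr([1, 2, 3, 4], [1, 1, 0, 0], [1, 1, 0, 0])


class TestSurvivalReport:
    def _cohort(self, beta, n=200, seed=8):
        cohort, _ = ds.simulate_cohort(
            ds.CohortSimConfig(
                gene_names=["G"], n_primary=0, n_metastatic=n,
                beta={"G": beta} if beta else {}, seed=seed,
            )
        )
        return cohort

    def test_hazardous_gene_detected(self):
        rep = survival_report(self._cohort(np.log(2)), "G")
        assert rep.cox.hr > 1
        assert rep.logrank_p < 0.05
        assert rep.groups.value_counts()["high"] == 50

    def test_number_at_risk_decreases(self):
        rep = survival_report(self._cohort(0.0), "G")
        for col in ("high", "low"):
            assert (np.diff(rep.n_at_risk[col]) <= 0).all()

    def test_small_cohort_propagates_dichotomization_error(self):
        cohort = make_cohort(
            {"G": [1.0, 2.0, 3.0]},
            os_months=[1, 2, 3],
            os_event=[1, 1, 1],
        )
        with pytest.raises(SurvivalError, match="8 samples"):
            survival_report(cohort, "G")
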