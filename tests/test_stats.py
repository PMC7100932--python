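"""Statistical battery tests.

Each test statistic is checked against an independent implementation written
directly from the defining formulas (Welch/Satterthwaite, OLS normal
equations, the hypergeometric log-rank life table) on small instances, plus
symmetry and degenerate-input behaviour.  Large-replicate type-I-error
calibration lives in the acceptance suite.
"""

import math

import numpy as np
import pytest

from piresponse import (km_curve, log_rank_test, run_primary_analysis,
                        slope_f_test, welch_t_test)

# ---------------------------------------------------------------------------
# independent oracles (formula-level reimplementations, no scipy/lifelines)
# ---------------------------------------------------------------------------

def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df


def ols_slope_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc = x - x.mean()
    slope = np.dot(xc, y) / np.dot(xc, xc)
    resid = y - (y.mean() + slope * xc)
    n = x.size
    se = math.sqrt(resid @ resid / (n - 2) / np.dot(xc, xc))
    return slope, (slope / se) ** 2  # slope, F = t^2


def logrank_oracle(ta, ea, tb, eb):
    """Hand life table: O-E with hypergeometric variance at each event time."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O = E = V = 0.0
    for t in event_times:
        n1, n2 = (ta >= t).sum(), (tb >= t).sum()
        d1, d2 = ((ta == t) & ea).sum(), ((tb == t) & eb).sum()
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def assert_3sf(a, b):
    assert a == pytest.approx(b, rel=5e-3)


# ---------------------------------------------------------------------------


class TestWelch:
    def test_identical_groups(self):
        r = welch_t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_separated_groups(self):
        r = welch_t_test([0, 0, 1, 1], [10, 10, 11, 11])
        assert r.p_value < 0.01
        assert r.direction == -1  # b > a
        t, _ = welch_oracle([0, 0, 1, 1], [10, 10, 11, 11])
        assert_3sf(r.statistic, t)
        assert t == pytest.approx(-10 / math.sqrt(1 / 6), rel=1e-9)  # hand value

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(2, 9))
        b = rng.normal(0.5, 2, rng.integers(2, 9))
        r = welch_t_test(a, b)
        t, _ = welch_oracle(a, b)
        assert_3sf(r.statistic, t)

    def test_label_swap_symmetry(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0, 9.0]
        assert welch_t_test(a, b).p_value == pytest.approx(
            welch_t_test(b, a).p_value, rel=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_constant_equal_groups_convention(self):
        with pytest.warns(UserWarning):
            r = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0


class TestSlopeF:
    def test_perfect_line(self):
        x = np.arange(1.0, 6.0)
        r = slope_f_test(x, 2 * x)
        assert r.estimate == pytest.approx(2.0, rel=1e-12)
        assert r.p_value < 1e-10

    def test_three_point_hand_case(self):
        r = slope_f_test([1, 2, 3], [1, 2, 2])
        slope, F = ols_slope_oracle([1, 2, 3], [1, 2, 2])
        assert r.estimate == pytest.approx(0.5, rel=1e-12)
        assert slope == pytest.approx(0.5, rel=1e-12)
        assert_3sf(r.statistic, F)

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_oracle_small_n(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 9))
        x = rng.normal(0, 1, n)
        y = 0.3 * x + rng.normal(0, 1, n)
        r = slope_f_test(x, y)
        slope, F = ols_slope_oracle(x, y)
        assert_3sf(r.estimate, slope)
        assert_3sf(r.statistic, F)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            slope_f_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLogRank:
    def test_identical_groups(self):
        t = [3.0, 5.0, 9.0]
        e = [True, True, False]
        r = log_rank_test(t, e, t, e)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_fully_separated_groups_match_hand_table(self):
        ta, tb = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        ea = eb = [True, True, True]
        r = log_rank_test(ta, ea, tb, eb)
        assert_3sf(r.statistic, logrank_oracle(ta, ea, tb, eb))

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_oracle_small_n(self, seed):
        rng = np.random.default_rng(200 + seed)
        na, nb = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        ta, tb = rng.exponential(10, na), rng.exponential(14, nb)
        ea, eb = rng.random(na) < 0.8, rng.random(nb) < 0.8
        if ea.sum() + eb.sum() == 0:
            ea[0] = True
        r = log_rank_test(ta, ea, tb, eb)
        assert_3sf(r.statistic, logrank_oracle(ta, ea, tb, eb))

    def test_label_swap_symmetry(self):
        ta, tb = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0, 11.0]
        ea, eb = [1, 1, 0], [1, 0, 1, 1]
        assert log_rank_test(ta, ea, tb, eb).p_value == pytest.approx(
            log_rank_test(tb, eb, ta, ea).p_value, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            log_rank_test([1.0], [False], [2.0], [False])


class TestKaplanMeier:
    def test_distinct_events_drop_one_over_n(self):
        c = km_curve([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        surv = dict(zip(c.times, c.survival_prob))
        assert surv[2.0] == pytest.approx(0.5)
        assert surv[4.0] == pytest.approx(0.0)

    def test_single_censored_subject_flat(self):
        c = km_curve([5.0], [False])
        assert np.all(c.survival_prob == 1.0)
        assert list(c.censor_times) == [5.0]

    def test_product_limit_hand_value(self):
        # events at 5 and 15, censoring at 10: S(5)=2/3, S(15)=0
        c = km_curve([5.0, 10.0, 15.0], [True, False, True])
        surv = dict(zip(c.times, c.survival_prob))
        assert surv[5.0] == pytest.approx(2 / 3)
        assert surv[15.0] == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestPrimaryAnalysis:
    def test_report_structure(self, default_metrics):
        rep = run_primary_analysis(default_metrics)
        assert {"analysis", "comparison", "p_value", "n_groups"} <= set(rep.columns)
        assert (rep["analysis"] == "tertile_cycles_response").sum() == 3
        est = rep["p_value"].dropna()
        assert ((est >= 0) & (est <= 1)).all()

    def test_planted_nodular_effect_recovered(self, default_metrics):
        rep = run_primary_analysis(default_metrics)
        nod = rep[rep["comparison"].str.startswith("nodular: cycles")].iloc[0]
        assert nod["p_value"] < 0.05 and nod["estimate"] < 0

    def test_missing_mgmt_reported_not_estimable(self, default_metrics):
        df = default_metrics.copy()
        df["mgmt_status"] = "not_available"
        rep = run_primary_analysis(df)
        mgmt = rep[rep["analysis"] == "mgmt"]
        assert len(mgmt) == 4
        assert mgmt["p_value"].isna().all()
        assert mgmt["note"].str.contains("not estimable").all()

    def test_sex_stratified_rerun_adds_strata(self, default_metrics):
        rep = run_primary_analysis(default_metrics, stratify_sex=True)
        assert set(rep["stratum"]) == {"all", "male", "female"}

    def test_nadir_variant_uses_nadir_response(self, default_metrics):
        rep = run_primary_analysis(default_metrics, nadir_variant=True)
        # nadir percent change is <= the post change, so responders can only gain
        n_resp_nadir = (default_metrics["pct_change_t1gd_nadir"] < 0).sum()
        n_resp = (default_metrics["pct_change_t1gd"] < 0).sum()
        assert n_resp_nadir >= n_resp
        assert len(rep) > 0
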