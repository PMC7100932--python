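"""Statistical battery: Welch t, slope F, log-rank, Kaplan-Meier, and the
stratified primary analysis (responder comparisons, tertile analyses, MGMT
subanalyses, optional sex-stratified / nadir-variant reruns).

Alpha = 0.05 is a reporting threshold only; no multiplicity correction is
applied, matching the source analyses.  Comparisons with an arm too small to
test are reported as not-estimable rows (p = NaN), never fabricated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

__all__ = [
    "StatResult",
    "SurvivalCurve",
    "welch_t_test",
    "slope_f_test",
    "log_rank_test",
    "km_curve",
    "run_primary_analysis",
]


@dataclass(frozen=True)
class StatResult:
    test_name: str  # welch_t | slope_F | log_rank
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    estimate: float | None = None  # mean difference (a - b) or slope
    direction: int | None = None   # sign of the estimate


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray


def welch_t_test(a, b) -> StatResult:
    """Two-sided unequal-variance t-test (Satterthwaite df); estimate = mean(a)-mean(b)."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >= 2 values (got {a.size}, {b.size})")
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if diff == 0:
            warnings.warn("both groups constant and equal: p = 1 by convention",
                          stacklevel=2)
            return StatResult("welch_t", 0.0, 1.0, (a.size, b.size), 0.0, 0)
        raise ValueError("both groups constant with different means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return StatResult("welch_t", float(res.statistic), float(res.pvalue),
                      (a.size, b.size), diff, int(np.sign(diff)))


def slope_f_test(x, y) -> StatResult:
    """OLS slope of y on x with the slope F-test (F = t^2), two-sided."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    res = sps.linregress(x, y)
    t = np.inf if res.stderr == 0 else res.slope / res.stderr
    return StatResult("slope_F", float(t**2), float(res.pvalue), (x.size,),
                      float(res.slope), int(np.sign(res.slope)) if res.slope else 0)


def log_rank_test(times_a, events_a, times_b, events_b) -> StatResult:
    """Two-group log-rank test (hypergeometric tie handling, chi-square, 1 df)."""
    ta = np.asarray(list(times_a), float)
    ea = np.asarray(list(events_a), bool)
    tb = np.asarray(list(times_b), float)
    eb = np.asarray(list(events_b), bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group: log-rank undefined")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return StatResult("log_rank", float(res.test_statistic), float(res.p_value),
                      (ta.size, tb.size))


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    t = np.asarray(list(times), float)
    e = np.asarray(list(events), bool)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    return SurvivalCurve(
        times=tbl.index.to_numpy(float),
        survival_prob=kmf.survival_function_["KM_estimate"].to_numpy(),
        at_risk=tbl["at_risk"].to_numpy(),
        censor_times=np.sort(t[~e]),
    )


# ---------------------------------------------------------------------------
# Primary analysis report
# ---------------------------------------------------------------------------

_MIN_ARM = 2  # smallest arm for which a two-group test is attempted


def _row(analysis, comparison, result: StatResult | None, note: str = "",
         stratum: str = "all") -> dict:
    base = {"stratum": stratum, "analysis": analysis, "comparison": comparison,
            "test": None, "statistic": np.nan, "p_value": np.nan,
            "n_groups": "", "estimate": np.nan, "note": note}
    if result is not None:
        base.update(test=result.test_name, statistic=result.statistic,
                    p_value=result.p_value,
                    n_groups="/".join(str(n) for n in result.n_per_group),
                    estimate=np.nan if result.estimate is None else result.estimate)
    return base


def _welch_or_na(analysis, comparison, a, b, stratum="all"):
    a = pd.Series(a).dropna().to_numpy(float)
    b = pd.Series(b).dropna().to_numpy(float)
    if a.size < _MIN_ARM or b.size < _MIN_ARM:
        return _row(analysis, comparison, None,
                    f"not estimable (n={a.size}/{b.size})", stratum)
    return _row(analysis, comparison, welch_t_test(a, b), stratum=stratum)


def _logrank_or_na(analysis, comparison, ta, ea, tb, eb, stratum="all"):
    if len(ta) < 1 or len(tb) < 1 or (np.sum(ea) + np.sum(eb)) == 0:
        return _row(analysis, comparison, None,
                    f"not estimable (n={len(ta)}/{len(tb)})", stratum)
    return _row(analysis, comparison, log_rank_test(ta, ea, tb, eb), stratum=stratum)


def _slope_or_na(analysis, comparison, x, y, stratum="all"):
    d = pd.DataFrame({"x": x, "y": y}).dropna()
    if len(d) < 3 or d["x"].nunique() < 2:
        return _row(analysis, comparison, None, f"not estimable (n={len(d)})", stratum)
    return _row(analysis, comparison, slope_f_test(d["x"], d["y"]), stratum=stratum)


def _analysis_block(df: pd.DataFrame, stratum: str, response_col: str,
                    retertile: bool = True) -> list[dict]:
    from .metrics import TERTILE_LABELS, assign_invasiveness_tertiles

    rows: list[dict] = []
    d = df.copy()
    d = d[d[response_col].notna()]
    d["is_responder"] = d[response_col] < 0
    resp = d[d["is_responder"]]
    non = d[~d["is_responder"]]

    # (i) responder vs non-responder characteristic comparisons (Welch)
    for label, col in [("age", "age"), ("cycles of TMZ", "cycles_tmz"),
                       ("proportion of adjuvant to nadir", "proportion_adjuvant_to_nadir"),
                       ("pre-adjuvant D/rho", "d_over_rho_mm2"),
                       ("pre-adjuvant T1Gd radius", "pre_t1gd_radius_mm"),
                       ("pre-adjuvant T2-FLAIR radius", "pre_t2flair_radius_mm")]:
        rows.append(_welch_or_na("responder_characteristics",
                                 f"{label}: responders vs non-responders",
                                 resp[col], non[col], stratum))

    # (ii) survival by responder status
    surv = d[d["os_days"].notna()]
    rs, ns = surv[surv["is_responder"]], surv[~surv["is_responder"]]
    rows.append(_logrank_or_na("survival", "overall survival: responders vs non-responders",
                               rs["os_days"], rs["death_observed"],
                               ns["os_days"], ns["death_observed"], stratum))
    prog = d[d["progression_days"].notna()]  # known progression dates only
    rp, np_ = prog[prog["is_responder"]], prog[~prog["is_responder"]]
    rows.append(_logrank_or_na("survival", "time to progression: responders vs non-responders",
                               rp["progression_days"], np.ones(len(rp), bool),
                               np_["progression_days"], np.ones(len(np_), bool), stratum))

    # (iii) within-tertile analyses (tertiles over this stratum's D/rho values,
    # or the precomputed full-cohort labels when retertile is off)
    have = d[d["d_over_rho_mm2"].notna()].copy()
    if len(have) >= 3:
        if retertile or "tertile" not in have.columns or have["tertile"].isna().all():
            grouping = assign_invasiveness_tertiles(have["d_over_rho_mm2"].to_numpy())
            have["tertile"] = grouping.labels
        for tert in TERTILE_LABELS:
            g = have[have["tertile"] == tert]
            rows.append(_slope_or_na(
                "tertile_cycles_response",
                f"{tert}: cycles vs pct-change T1Gd (slope)",
                g["cycles_tmz"], g[response_col], stratum))
            gr, gn = g[g["is_responder"]], g[~g["is_responder"]]
            rows.append(_logrank_or_na(
                "tertile_survival",
                f"{tert}: overall survival responders vs non-responders",
                gr["os_days"], gr["death_observed"],
                gn["os_days"], gn["death_observed"], stratum))

    # (iv) MGMT subanalyses when status is available
    mg = d[d["mgmt_status"].isin(["methylated", "unmethylated"])]
    me, un = mg[mg["mgmt_status"] == "methylated"], mg[mg["mgmt_status"] == "unmethylated"]
    rows.append(_logrank_or_na("mgmt", "overall survival: methylated vs unmethylated",
                               me["os_days"], me["death_observed"],
                               un["os_days"], un["death_observed"], stratum))
    rows.append(_welch_or_na("mgmt", "pre-adjuvant D/rho: methylated vs unmethylated",
                             me["d_over_rho_mm2"], un["d_over_rho_mm2"], stratum))
    rows.append(_welch_or_na("mgmt", "cycles of TMZ: methylated vs unmethylated",
                             me["cycles_tmz"], un["cycles_tmz"], stratum))
    rows.append(_welch_or_na("mgmt", "pct-change T1Gd: methylated vs unmethylated",
                             me[response_col], un[response_col], stratum))
    return rows


def run_primary_analysis(
    metrics_df: pd.DataFrame,
    *,
    stratify_sex: bool = False,
    nadir_variant: bool = False,
    retertile_per_stratum: bool = True,
) -> pd.DataFrame:
    """The full stratified comparison battery over a per-patient metrics table.

    Input is the table from :func:`piresponse.metrics.cohort_metrics`.  Returns
    a tidy report: one row per comparison with test, statistic, p-value, group
    sizes and an estimate where meaningful.  With ``stratify_sex`` the battery
    is rerun within each sex (re-tertiled per stratum by default, so group
    sizes mirror a within-sex three-way split); ``nadir_variant`` swaps the
    response variable for the pre-to-nadir percent change.
    """
    response_col = "pct_change_t1gd_nadir" if nadir_variant else "pct_change_t1gd"
    if response_col not in metrics_df.columns:
        raise ValueError(f"metrics table lacks {response_col}")
    rows = _analysis_block(metrics_df, "all", response_col)
    if stratify_sex:
        for sex in ("male", "female"):
            sub = metrics_df[metrics_df["sex"] == sex]
            rows.extend(_analysis_block(sub, sex, response_col,
                                        retertile=retertile_per_stratum))
    report = pd.DataFrame(rows)
    report["significant"] = report["p_value"] < 0.05
    return report


def report_p_values(report: pd.DataFrame) -> np.ndarray:
    """All estimable p-values of an analysis report (helper for calibration checks)."""
    return report["p_value"].dropna().to_numpy(float)
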