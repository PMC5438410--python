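"""Cohort rules, product-limit estimation, log-rank, Cox, report assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from pnetquant import survival_analysis as sa
from pnetquant import synthetic_data as sd
from pnetquant.survival_analysis import AnalysisError, SurvivalObservation
from pnetquant.tabular_io import SubjectRecord


def subj(sid, status, fu=24.0, **kw):
    defaults = dict(subject_id=sid, status=status, followup_months=fu,
                    uchl1_percent=80.0, inx_percent=80.0)
    defaults.update(kw)
    return SubjectRecord(**defaults)


# ---------------------------------------------------------------------------
# cohort preparation
# ---------------------------------------------------------------------------

def test_prepare_survival_endpoint_rules():
    subjects = [subj("a", "DFS"), subj("b", "AWD"), subj("c", "DOD"),
                subj("d", "DUC")]
    os_obs = sa.prepare_survival(subjects, "OS")
    assert [o.subject_id for o in os_obs] == ["a", "b", "c"]  # DUC dropped
    assert [o.event for o in os_obs] == [False, False, True]
    dfs_obs = sa.prepare_survival(subjects, "DFS")
    assert [o.event for o in dfs_obs] == [False, True, True]


def test_prepare_survival_excludes_unknown_and_lost():
    subjects = [subj("a", "DFS"), subj("b", "lost", fu=None),
                subj("c", "alive_unknown"), subj("d", None)]
    obs = sa.prepare_survival(subjects, "OS")
    assert [o.subject_id for o in obs] == ["a"]
    assert sa.prepare_survival.last_excluded == 3


def test_prepare_survival_duc_exclusion_at_cohort_scale():
    rng = np.random.default_rng(9)
    subjects = [subj(f"s{i}", "DFS", fu=float(rng.integers(1, 100)))
                for i in range(237)]
    subjects += [subj(f"d{i}", "DUC") for i in range(10)]
    obs = sa.prepare_survival(subjects, "OS")
    assert len(obs) == 237


def test_prepare_survival_empty_errors():
    with pytest.raises(AnalysisError):
        sa.prepare_survival([subj("a", "DUC")], "OS")
    with pytest.raises(AnalysisError):
        sa.prepare_survival([subj("a", "DFS")], "PFS")


def test_marker_status_rules():
    assert sa.marker_status(subj("a", "DFS")).concurrent == "present"
    assert sa.marker_status(
        subj("a", "DFS", inx_percent=5.0)).concurrent == "absent"
    assert sa.marker_status(
        subj("a", "DFS", inx_percent=None)).concurrent == "missing"
    st = sa.marker_status(subj("a", "DFS", uchl1_percent=19.9))
    assert st.uchl1 == "negative" and st.concurrent == "absent"


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_hand_product_limit():
    obs = [SurvivalObservation(str(i), t, True) for i, t in enumerate([1, 2, 3])]
    c = sa.km_curve(obs)
    assert np.allclose(c.times, [0, 1, 2, 3])
    assert np.allclose(c.survival, [1.0, 2 / 3, 1 / 3, 0.0])
    assert list(c.at_risk) == [3, 3, 2, 1]


def test_km_all_censored_and_single_event():
    cens = [SurvivalObservation(str(i), t, False)
            for i, t in enumerate([5, 10, 15])]
    assert np.allclose(sa.km_curve(cens).survival, 1.0)
    single = sa.km_curve([SurvivalObservation("x", 5, True)])
    assert single.survival_at(5.0) == pytest.approx(0.0)


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(12)
    times = rng.exponential(20, 150)
    obs = [SurvivalObservation(str(i), t, True) for i, t in enumerate(times)]
    c = sa.km_curve(obs)
    for t in np.quantile(times, [0.1, 0.25, 0.5, 0.75, 0.9]):
        assert c.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)


def test_negative_time_rejected():
    with pytest.raises(Exception):
        SurvivalObservation("x", -1.0, True)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_null():
    g = [SurvivalObservation(str(i), t, True)
         for i, t in enumerate([1, 3, 5, 7])]
    g2 = [SurvivalObservation("b" + str(i), o.time, o.event)
          for i, o in enumerate(g)]
    res = sa.logrank([g, g2])
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_logrank_hand_computed_o_minus_e():
    # events A at {1,2}, B at {3,4}; O_A=2, E_A=1/2+1/3, V=1/4+2/9:
    # chi2 = (2 - 5/6)^2 / (17/36) = 49/36 * 36/17 = 49/17
    a = [SurvivalObservation("a1", 1, True), SurvivalObservation("a2", 2, True)]
    b = [SurvivalObservation("b1", 3, True), SurvivalObservation("b2", 4, True)]
    res = sa.logrank([a, b])
    assert res.statistic == pytest.approx(49 / 17, abs=1e-9)
    assert res.statistic == pytest.approx(2.8824, abs=1e-4)


def test_logrank_two_groups_equals_squared_standardized_oe():
    """Internal consistency: the 2-group statistic is (O-E)^2/V computed
    from the pooled risk-set table."""
    rng = np.random.default_rng(31)
    a = [SurvivalObservation(f"a{i}", t, True)
         for i, t in enumerate(rng.exponential(10, 25))]
    b = [SurvivalObservation(f"b{i}", t, bool(e)) for i, (t, e) in
         enumerate(zip(rng.exponential(14, 25), rng.random(25) < 0.8))]
    res = sa.logrank([a, b])
    # hand O-E accumulation over pooled event times
    times = sorted({o.time for o in a + b if o.event})
    O = E = V = 0.0
    for t in times:
        n1 = sum(o.time >= t for o in a)
        n = n1 + sum(o.time >= t for o in b)
        d = sum(o.time == t and o.event for o in a + b)
        d1 = sum(o.time == t and o.event for o in a)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    assert res.statistic == pytest.approx((O - E) ** 2 / V, rel=1e-9)


def test_logrank_requires_events_and_groups():
    g = [SurvivalObservation("a", 5, False)]
    with pytest.raises(AnalysisError):
        sa.logrank([g, [SurvivalObservation("b", 6, False)]])
    with pytest.raises(AnalysisError):
        sa.logrank([g])


def test_logrank_type_one_error_calibration():
    """Null simulation: exponential survival, equal hazards, n=200/arm."""
    rng = np.random.default_rng(3)
    rej = 0
    B = 1000
    from lifelines.statistics import logrank_test
    for _ in range(B):
        t1, t2 = rng.exponential(10, 200), rng.exponential(10, 200)
        rej += logrank_test(t1, t2).p_value <= 0.05
    assert 0.035 <= rej / B <= 0.065


# ---------------------------------------------------------------------------
# Cox model
# ---------------------------------------------------------------------------

def test_cox_partial_likelihood_hand_oracle():
    """4 subjects, binary covariate, no ties: lifelines' log-likelihood at
    the MLE equals the hand-enumerated risk-set product."""
    times, events, x = [1.0, 2.0, 3.0, 4.0], [True, True, True, False], \
        [1.0, 0.0, 1.0, 0.0]
    obs = [SurvivalObservation(f"s{i}", times[i], events[i]) for i in range(4)]
    X = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(4)])
    fit = sa.cox_fit(obs, X)
    beta = fit.coefficients["x"]

    def hand_pl(beta):
        ll = 0.0
        for i in range(4):
            if not events[i]:
                continue
            risk = [math.exp(beta * x[j]) for j in range(4)
                    if times[j] >= times[i]]
            ll += beta * x[i] - math.log(sum(risk))
        return ll

    assert fit.log_likelihood == pytest.approx(hand_pl(beta), abs=1e-9)
    assert fit.hazard_ratios["x"] == pytest.approx(math.exp(beta))
    assert fit.ci_lower["x"] < fit.hazard_ratios["x"] < fit.ci_upper["x"]


def test_cox_null_covariate_hr_near_one():
    rng = np.random.default_rng(21)
    tm = rng.exponential(10, 500)
    cv = rng.binomial(1, 0.5, 500).astype(float)
    obs = [SurvivalObservation(f"s{i}", tm[i], True) for i in range(500)]
    X = pd.DataFrame({"x": cv}, index=[f"s{i}" for i in range(500)])
    fit = sa.cox_fit(obs, X)
    assert 0.85 <= fit.hazard_ratios["x"] <= 1.18
    assert fit.converged


def test_cox_recovers_synthetic_hazard_ratio():
    """HR 0.2 for marker-present patients at n=500 is recovered within 25%."""
    log_hrs = []
    for rep in range(5):
        spec = sd.SimulationSpec(
            seed=100 + rep, n_subjects=500, p_marker_missing=0.0,
            p_uchl1_positive=0.55, p_inx_positive=0.55, hr_os=0.2,
            baseline_hazard_os=0.03, censor_window=(1.0, 120.0),
            p_followed=1.0, p_duc=0.0)
        cohort = sd.simulate_cohort(spec)
        obs = sa.prepare_survival(cohort, "OS", group_by="concurrent")
        X = pd.DataFrame(
            {"present": [1.0 if o.group == "present" else 0.0 for o in obs]},
            index=[o.subject_id for o in obs])
        log_hrs.append(math.log(sa.cox_fit(obs, X).hazard_ratios["present"]))
    recovered = math.exp(np.mean(log_hrs))
    assert 0.15 <= recovered <= 0.25


def test_cox_constant_covariate_rejected():
    obs = [SurvivalObservation(f"s{i}", float(i + 1), True) for i in range(4)]
    X = pd.DataFrame({"x": [1.0] * 4}, index=[f"s{i}" for i in range(4)])
    with pytest.raises(AnalysisError):
        sa.cox_fit(obs, X)


# ---------------------------------------------------------------------------
# subgroups and the cross-sectional report
# ---------------------------------------------------------------------------

def test_subgroup_filter_stage_and_subtype():
    subjects = [subj(f"s{i}", "DFS", stage=st)
                for i, st in enumerate(["I", "IIa", "IIb", "III", "IV"])]
    assert [s.stage for s in sa.subgroup_filter(subjects, "stage_II_III")] == \
        ["IIa", "IIb", "III"]
    mixed = [subj("a", "DFS", subtype="insulinoma"),
             subj("b", "DFS", subtype="non_insulinoma")]
    assert [s.subject_id for s in sa.subgroup_filter(mixed, "insulinoma")] == ["a"]
    assert sa.subgroup_filter(mixed, "combined") == mixed


def test_subgroup_filter_published_stage_proportions():
    counts = {"I": 95, "IIa": 98, "IIb": 34, "III": 31, "IV": 47}
    subjects = []
    i = 0
    for stg, n in counts.items():
        for _ in range(n):
            subjects.append(subj(f"s{i}", "DFS", stage=stg))
            i += 1
    assert len(sa.subgroup_filter(subjects, "stage_II_III")) == 163


def test_clinicopath_report_counts_and_null_feature(default_cohort):
    rep = sa.clinicopath_report(default_cohort)
    assert set(rep["feature"]) >= {"age", "sex", "stage", "death",
                                   "recurrence", "disease_free_survival"}
    # no silent drops: strata sizes match the computable-status subjects
    n_statused = sum(
        1 for s in default_cohort
        if sa.marker_status(s).concurrent in ("present", "absent"))
    age_row = rep[rep["feature"] == "age"].iloc[0]
    assert age_row["n_present"] + age_row["n_absent"] == n_statused
    # survival rows exclude DUC and unfollowed subjects
    death_row = rep[rep["feature"] == "death"].iloc[0]
    n_followed = sum(
        1 for s in default_cohort
        if s.status in ("DFS", "AWD", "DOD")
        and sa.marker_status(s).concurrent in ("present", "absent"))
    assert death_row["n_present"] + death_row["n_absent"] == n_followed
    assert ((rep["p_value"].dropna() >= 0) & (rep["p_value"].dropna() <= 1)).all()


def test_clinicopath_report_identical_feature_p_one():
    subjects = [subj(f"s{i}", "DFS", sex="female",
                     inx_percent=80.0 if i % 2 else 5.0) for i in range(20)]
    rep = sa.clinicopath_report(subjects)
    sex_row = rep[rep["feature"] == "sex"].iloc[0]
    assert sex_row["method"] == "none" or sex_row["p_value"] == pytest.approx(1.0)
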