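"""Cohort preparation, Kaplan-Meier / log-rank / Cox analyses, and the
cross-sectional clinicopathology report for single and concurrent biomarkers.

Endpoints follow the study's outcome coding: follow-up runs from surgery to
recurrence, death or last contact; patients who died of unknown cause (DUC)
are excluded from both endpoints, as are patients without usable follow-up.
Overall survival (OS) counts death of disease (DOD) as the event;
disease-free survival (DFS) counts recurrence or death of disease (AWD or
DOD) as the event.  Concurrent biomarker status is present only when both
markers are IHC-positive (>= 20% stained cells), absent when both are
scored and at least one is negative, and missing when either score is
unavailable.

Estimation is delegated to lifelines (product-limit estimator, log-rank
test, Cox partial likelihood with Efron tie handling); this module owns the
cohort rules and report assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .assay_validation import classify_ihc
from .exact_stats import (ContingencyTable2x2, StatTestError, TestResult,
                          chi_square_rxc, fisher_exact_2x2,
                          mann_whitney_exact)
from .tabular_io import SubjectRecord, ValidationError


class AnalysisError(ValueError):
    """No eligible subjects, or a test precondition fails for the cohort."""


@dataclass
class SurvivalObservation:
    subject_id: str
    time: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(
                f"subject {self.subject_id}: negative survival time")


@dataclass
class MarkerStatus:
    uchl1: str
    inx: str
    concurrent: str


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass
class CoxFit:
    coefficients: Dict[str, float]
    hazard_ratios: Dict[str, float]
    ci_lower: Dict[str, float]
    ci_upper: Dict[str, float]
    p_values: Dict[str, float]
    log_likelihood: float
    converged: bool


# ---------------------------------------------------------------------------
# cohort rules
# ---------------------------------------------------------------------------

_EXCLUDED_STATUSES = {"DUC", "alive_unknown", "lost", None}
_EVENT_STATUSES = {"OS": {"DOD"}, "DFS": {"AWD", "DOD"}}


def marker_status(subject: SubjectRecord,
                  threshold: float = 20.0) -> MarkerStatus:
    """Derive per-marker and concurrent expression status from IHC percentages."""
    def call(pct: Optional[float]) -> str:
        return "missing" if pct is None else classify_ihc(pct)

    u, i = call(subject.uchl1_percent), call(subject.inx_percent)
    if u == "missing" or i == "missing":
        concurrent = "missing"
    elif u == "positive" and i == "positive":
        concurrent = "present"
    else:
        concurrent = "absent"
    return MarkerStatus(uchl1=u, inx=i, concurrent=concurrent)


def prepare_survival(subjects: Sequence[SubjectRecord],
                     endpoint: str,
                     group_by: Optional[str] = None) -> List[SurvivalObservation]:
    """Turn subject records into (time, event) observations for one endpoint.

    Excluded with a logged count: deaths of unknown cause, subjects with
    unknown/absent outcome status, and subjects without follow-up time.
    ``group_by`` may name a marker stratum: ``"uchl1"``, ``"inx"`` or
    ``"concurrent"`` (subjects with missing status are then also excluded).
    """
    if endpoint not in _EVENT_STATUSES:
        raise AnalysisError(f"endpoint must be OS or DFS, got {endpoint!r}")
    events = _EVENT_STATUSES[endpoint]
    obs: List[SurvivalObservation] = []
    n_excluded = 0
    for s in subjects:
        if s.status in _EXCLUDED_STATUSES or s.followup_months is None:
            n_excluded += 1
            continue
        group = ""
        if group_by is not None:
            st = getattr(marker_status(s), group_by)
            if st == "missing":
                n_excluded += 1
                continue
            group = st
        obs.append(SurvivalObservation(
            subject_id=s.subject_id, time=float(s.followup_months),
            event=s.status in events, group=group))
    if not obs:
        raise AnalysisError(
            f"no eligible subjects for endpoint {endpoint} "
            f"({n_excluded} excluded)")
    prepare_survival.last_excluded = n_excluded  # audit hook
    return obs


# ---------------------------------------------------------------------------
# estimators (lifelines-backed)
# ---------------------------------------------------------------------------

def km_curve(observations: Sequence[SurvivalObservation]) -> KMCurve:
    """Product-limit (Kaplan-Meier) survival estimate.

    S(0) = 1; each event time multiplies by (1 - d_i / n_i); censoring
    shrinks the risk set without a step.
    """
    if not observations:
        raise AnalysisError("no observations")
    times = np.array([o.time for o in observations])
    events = np.array([o.event for o in observations], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([(times >= t).sum() for t in grid])
    return KMCurve(times=grid, survival=surv, at_risk=at_risk)


def logrank(groups: Sequence[Sequence[SurvivalObservation]]) -> TestResult:
    """k-sample log-rank test (chi-square with k-1 df, two-sided)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise AnalysisError("log-rank needs >= 2 non-empty groups")
    if not any(o.event for g in groups for o in g):
        raise AnalysisError("no events in any group: log-rank undefined")
    times, events, labels = [], [], []
    for gi, g in enumerate(groups):
        for o in g:
            times.append(o.time)
            events.append(o.event)
            labels.append(gi)
    res = multivariate_logrank_test(np.asarray(times), np.asarray(labels),
                                    np.asarray(events, dtype=bool))
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value), method="logrank",
                      extra={"df": len(groups) - 1})


def cox_fit(observations: Sequence[SurvivalObservation],
            covariates: pd.DataFrame) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Wald CIs and p-values).

    ``covariates`` is indexed by subject_id with one numeric column per
    covariate.  Constant covariates are rejected; a monotone partial
    likelihood (complete separation) surfaces as ``converged=False`` rather
    than a silent answer.
    """
    if not any(o.event for o in observations):
        raise AnalysisError("no events: Cox model undefined")
    idx = [o.subject_id for o in observations]
    missing = [i for i in idx if i not in covariates.index]
    if missing:
        raise AnalysisError(f"covariates missing for subjects {missing[:5]}...")
    X = covariates.loc[idx].astype(float)
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise AnalysisError(f"constant covariate {col!r}")
    df = X.copy()
    df["time"] = [o.time for o in observations]
    df["event"] = [int(o.event) for o in observations]
    cph = CoxPHFitter()
    converged = True
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as err:  # convergence failure / separation
        raise AnalysisError(f"Cox fit failed: {err}") from err
    # lifelines warns (rather than raises) on near-separation; flag huge SEs
    if (cph.standard_errors_.abs() > 1e3).any():
        converged = False
    summary = cph.summary
    return CoxFit(
        coefficients=summary["coef"].to_dict(),
        hazard_ratios=summary["exp(coef)"].to_dict(),
        ci_lower=summary["exp(coef) lower 95%"].to_dict(),
        ci_upper=summary["exp(coef) upper 95%"].to_dict(),
        p_values=summary["p"].to_dict(),
        log_likelihood=float(cph.log_likelihood_),
        converged=converged)


# ---------------------------------------------------------------------------
# subgroups and the cross-sectional report
# ---------------------------------------------------------------------------

_SUBGROUP_RULES = {
    "stage_II_III": lambda s: s.stage in ("IIa", "IIb", "III"),
    "insulinoma": lambda s: s.subtype == "insulinoma",
    "non_insulinoma": lambda s: s.subtype == "non_insulinoma",
    "functional": lambda s: s.functional == "functional",
    "nonfunctional": lambda s: s.functional == "nonfunctional",
    "cohort_I": lambda s: s.cohort == "I",
    "cohort_II": lambda s: s.cohort == "II",
    "combined": lambda s: True,
}


def subgroup_filter(subjects: Sequence[SubjectRecord],
                    rule: str) -> List[SubjectRecord]:
    """Filter the cohort by a named clinical subgroup; filters compose."""
    if rule not in _SUBGROUP_RULES:
        raise AnalysisError(
            f"unknown subgroup rule {rule!r}; choose from {sorted(_SUBGROUP_RULES)}")
    pred = _SUBGROUP_RULES[rule]
    return [s for s in subjects if pred(s)]


def _categorical_row(values_present: list, values_absent: list,
                     feature: str) -> dict:
    levels = sorted(set(values_present) | set(values_absent))
    table = np.array([[values_present.count(l) for l in levels],
                      [values_absent.count(l) for l in levels]])
    # drop empty levels to keep margins positive
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return {"feature": feature, "method": "none", "statistic": math.nan,
                "p_value": math.nan,
                "n_present": len(values_present), "n_absent": len(values_absent)}
    if table.shape[1] == 2:
        res = fisher_exact_2x2(ContingencyTable2x2.from_rows(table))
    else:
        res = chi_square_rxc(table)
    return {"feature": feature, "method": res.method,
            "statistic": res.statistic, "p_value": res.p_value,
            "n_present": len(values_present), "n_absent": len(values_absent)}


def _continuous_row(values_present: list, values_absent: list,
                    feature: str) -> dict:
    if not values_present or not values_absent:
        return {"feature": feature, "method": "none", "statistic": math.nan,
                "p_value": math.nan,
                "n_present": len(values_present), "n_absent": len(values_absent)}
    res = mann_whitney_exact(values_present, values_absent)
    return {"feature": feature, "method": res.method,
            "statistic": res.statistic, "p_value": res.p_value,
            "n_present": len(values_present), "n_absent": len(values_absent)}


def clinicopath_report(subjects: Sequence[SubjectRecord],
                       marker: str = "concurrent") -> pd.DataFrame:
    """Cross-sectional association of clinical features with marker status.

    One row per feature: counts by status, test used (Fisher for 2x2,
    chi-square for r x c, exact Mann-Whitney for continuous) and the
    two-sided p-value.  Deaths of unknown cause are excluded only from the
    survival-outcome rows; every row's counts sum to the subjects eligible
    for that row.
    """
    strat: Dict[str, List[SubjectRecord]] = {"present": [], "absent": []}
    for s in subjects:
        st = getattr(marker_status(s), marker)
        if marker != "concurrent":
            st = {"positive": "present", "negative": "absent"}.get(st, st)
        if st in strat:
            strat[st].append(s)
    pres, absn = strat["present"], strat["absent"]
    if not pres or not absn:
        raise AnalysisError("marker status not computable for both strata")

    rows = []
    rows.append(_continuous_row(
        [s.age for s in pres if s.age is not None],
        [s.age for s in absn if s.age is not None], "age"))
    rows.append(_categorical_row(
        [s.sex for s in pres if s.sex], [s.sex for s in absn if s.sex], "sex"))
    for feat in ("grade", "stage", "ki67_class", "location"):
        rows.append(_categorical_row(
            [getattr(s, feat) for s in pres if getattr(s, feat) != "unknown"],
            [getattr(s, feat) for s in absn if getattr(s, feat) != "unknown"],
            feat))
    rows.append(_categorical_row(
        [s.metastasis for s in pres if s.metastasis is not None],
        [s.metastasis for s in absn if s.metastasis is not None], "metastasis"))
    rows.append(_continuous_row(
        [s.size_cm for s in pres if s.size_cm is not None],
        [s.size_cm for s in absn if s.size_cm is not None], "size_cm"))

    # survival-outcome rows: DUC (and unknown-status) subjects excluded
    def followed(group):
        return [s for s in group if s.status in ("DFS", "AWD", "DOD")]

    fp, fa = followed(pres), followed(absn)
    rows.append(_categorical_row(
        [s.status == "DOD" for s in fp], [s.status == "DOD" for s in fa],
        "death"))
    rows.append(_categorical_row(
        [s.status in ("AWD", "DOD") for s in fp],
        [s.status in ("AWD", "DOD") for s in fa], "recurrence"))
    rows.append(_categorical_row(
        [s.status == "DFS" for s in fp], [s.status == "DFS" for s in fa],
        "disease_free_survival"))
    return pd.DataFrame(rows)
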