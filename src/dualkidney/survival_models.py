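"""Kaplan-Meier, log-rank, and Cox proportional-hazards estimation for the
three transplant endpoints.

Endpoints: patient survival (death from any cause), all-cause graft survival
(graft failure or death, whichever first), and death-censored graft survival
(death with a functioning graft censors follow-up). Kaplan-Meier curves and
the two-group log-rank test come from lifelines; Cox models maximize the
partial likelihood with Efron handling of tied event times (registry
follow-up is coarsely recorded, so ties are expected). Confidence intervals
are Wald: exp(coef +/- 1.96 * se).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from ._design import build_design_matrix, check_full_rank

Z95 = 1.96


class CoxConvergenceError(RuntimeError):
    """Monotone partial likelihood or failed Newton iterations."""


@dataclass
class EndpointSpec:
    """How to read one time-to-event endpoint off the registry frame."""

    name: str
    time_field: str
    event_field: str
    censoring_rule: str = ""

    def extract(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        if self.name == "all_cause_graft":
            # first of graft failure and death; follow-up for graft failure is
            # already capped at death, so death-first shows as equal times
            time = df["time_graftfail"].to_numpy(dtype=float)
            event = (df["event_graftfail"].to_numpy(dtype=bool)
                     | (df["event_death"].to_numpy(dtype=bool)
                        & (df["time_death"].to_numpy(dtype=float) <= time)))
            return time, event
        return (df[self.time_field].to_numpy(dtype=float),
                df[self.event_field].to_numpy(dtype=bool))


ENDPOINTS = {
    "patient_survival": EndpointSpec(
        "patient_survival", "time_death", "event_death",
        "administrative censoring at last follow-up"),
    "all_cause_graft": EndpointSpec(
        "all_cause_graft", "time_graftfail", "event_graftfail",
        "graft failure or death, whichever first; administrative censoring"),
    "death_censored_graft": EndpointSpec(
        "death_censored_graft", "time_graftfail", "event_graftfail",
        "death with functioning graft censors follow-up"),
}

#: multivariable adjustment set: donor, recipient, and transplant factors
DEFAULT_ADJUSTMENT_COVARIATES = [
    "pump", "kdri", "donor_female", "cit_hours", "glomerulosclerosis",
    "inotropic_support", "epts", "dialysis_group", "pvd", "renal_diagnosis",
    "bmi", "cpra", "abo_incompatible", "hla_mismatch", "induction",
    "steroids_maintenance",
]


@dataclass
class SurvivalFit:
    """Product-limit curve for one group: right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    group: str = ""
    greenwood_var: np.ndarray = field(default=None, repr=False)
    max_time: float = 0.0

    def survival_at(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        out = np.where(idx < 0, 1.0, np.r_[1.0, self.survival][idx + 1])
        return float(out[0]) if np.isscalar(t) else out

    def variance_at(self, t) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_var[idx])

    def at_risk_at(self, t) -> int:
        """Number still at risk just after time t."""
        return int((self._raw_times > t).sum())


def kaplan_meier(times, events, group: str = "") -> SurvivalFit:
    """Product-limit estimator; survival queried at arbitrary times by
    right-continuous step interpolation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table[kmf.event_table["observed"] > 0]
    t = tab.index.to_numpy(dtype=float)
    s = kmf.survival_function_.loc[t, "KM_estimate"].to_numpy(dtype=float)
    # Greenwood variance: S(t)^2 * cumsum d / (n (n - d))
    d = tab["observed"].to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    gw = s ** 2 * np.cumsum(d / (n * (n - d)).clip(min=np.finfo(float).tiny))
    at_risk = tab["at_risk"].to_numpy(dtype=int)
    fit = SurvivalFit(times=t, survival=s, at_risk=at_risk, group=group,
                      greenwood_var=gw, max_time=float(times.max()))
    fit._raw_times = times
    return fit


def km_by_group(df: pd.DataFrame, endpoint: EndpointSpec,
                group_col: str = "group") -> dict:
    fits = {}
    for g, sub in df.groupby(group_col, observed=True):
        t, e = endpoint.extract(sub)
        fits[g] = kaplan_meier(t, e, group=str(g))
    return fits


def log_rank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square on 1 df -> (statistic, p_value, degenerate)."""
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("both groups must be nonempty")
    if not ea.any() and not eb.any():
        return 0.0, float("nan"), True
    res = _ll_logrank(times_a, times_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value), False


@dataclass
class CoxFit:
    coefficients: dict
    se: dict
    hazard_ratios: dict
    ci95: dict  # term -> (low, high) on the HR scale
    p_values: dict
    ties_method: str
    log_partial_likelihood: float
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        rows = [{"term": k, "coef": self.coefficients[k], "se": self.se[k],
                 "hr": self.hazard_ratios[k], "ci_low": self.ci95[k][0],
                 "ci_high": self.ci95[k][1], "p_value": self.p_values[k]}
                for k in self.coefficients]
        return pd.DataFrame(rows)


def cox_fit(df: pd.DataFrame, endpoint: EndpointSpec,
            covariates: list[str] | None = None,
            group_col: str = "group") -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) of the endpoint on the
    dual-vs-single indicator plus ``covariates`` (univariable when empty)."""
    covariates = list(covariates or [])
    time, event = endpoint.extract(df)
    if not event.any():
        raise CoxConvergenceError("no events observed for endpoint "
                                  f"{endpoint.name!r}")
    X = build_design_matrix(df, covariates)
    X = X.loc[:, X.nunique() > 1]  # rare levels may be absent in a subset
    X.insert(0, "group[dual]", (df[group_col] == "dual").astype(float).to_numpy())
    check_full_rank(X, with_intercept=False)
    data = X.copy()
    data["_time"] = np.maximum(time, 1e-9)
    data["_event"] = event.astype(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            # divergence is detected explicitly below
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise CoxConvergenceError(str(exc)) from exc
    coefs = cph.params_.to_dict()
    ses = cph.standard_errors_.to_dict()
    # a diverging group coefficient (flat likelihood direction) means the
    # group effect is not estimable; nuisance terms may keep wide CIs
    if abs(coefs["group[dual]"]) > 15 or ses["group[dual]"] > 1e3:
        raise CoxConvergenceError(
            "monotone likelihood: group coefficient diverged")
    with np.errstate(over="ignore"):  # a degenerate term may have inf CI
        ci = {k: (float(np.exp(coefs[k] - Z95 * ses[k])),
                  float(np.exp(coefs[k] + Z95 * ses[k]))) for k in coefs}
    return CoxFit(
        coefficients={k: float(v) for k, v in coefs.items()},
        se={k: float(v) for k, v in ses.items()},
        hazard_ratios={k: float(np.exp(v)) for k, v in coefs.items()},
        ci95=ci,
        p_values={k: float(v) for k, v in cph.summary["p"].to_dict().items()},
        ties_method="efron",
        log_partial_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=int(event.sum()),
    )


def survival_table(fits: dict, query_years, df: pd.DataFrame | None = None,
                   endpoint: EndpointSpec | None = None) -> pd.DataFrame:
    """Per-year survival percent and at-risk counts for the dual and single
    curves, with a pointwise normal-approximation p-value per year (Greenwood
    variances). Years beyond a curve's follow-up are flagged not-estimable.
    """
    dual, single = fits["dual"], fits["single"]
    rows = []
    for t in query_years:
        row = {"year": t}
        estimable = True
        for g, fit in (("dual", dual), ("single", single)):
            if t > fit.max_time:
                row[f"{g}_pct"], row[f"{g}_at_risk"] = np.nan, 0
                estimable = False
            else:
                row[f"{g}_pct"] = 100.0 * fit.survival_at(t)
                row[f"{g}_at_risk"] = fit.at_risk_at(t)
        if estimable and t > 0:
            se = np.sqrt(dual.variance_at(t) + single.variance_at(t))
            if se > 0:
                z = (dual.survival_at(t) - single.survival_at(t)) / se
                from scipy.stats import norm
                row["p_value"] = float(2 * norm.sf(abs(z)))
            else:
                row["p_value"] = np.nan
        else:
            row["p_value"] = np.nan
        row["not_estimable"] = not estimable
        rows.append(row)
    return pd.DataFrame(rows)
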