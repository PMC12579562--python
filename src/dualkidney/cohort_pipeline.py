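"""Cohort construction: entry-criteria filtering, single imputation, and
group-comparison descriptive statistics.

Entry criteria (applied in a fixed, documented order; a record failing
several rules is counted once under the first): adult recipient (>= 18
years), deceased donor, not an en bloc transplant, kidney donor risk index
(KDRI) recorded, survival follow-up recorded.

Missing-data policy is single deterministic imputation: BMI by least-squares
regression on recipient age, sex, and race/ethnicity; cold ischemia time by
least-squares regression on sharing breadth and donor-to-center distance;
length of stay by the observed median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._design import build_design_matrix, is_categorical

#: exclusion rules in application order: (name, predicate on the frame)
FILTER_RULES = [
    ("recipient_under_18", lambda df: df["recipient_age"] < 18),
    ("living_donor", lambda df: df["living_donor"].astype(bool)),
    ("en_bloc", lambda df: df["en_bloc"].astype(bool)),
    ("missing_kdri", lambda df: df["kdri"].isna()),
    ("missing_survival", lambda df: df["time_death"].isna()
     | df["time_graftfail"].isna()),
]


class ImputationError(ValueError):
    """A field cannot be imputed (e.g. no observed values)."""


@dataclass
class CohortFilterReport:
    n_input: int
    n_excluded_by_rule: dict = field(default_factory=dict)
    n_output: int = 0

    def validate(self) -> None:
        assert self.n_output == self.n_input - sum(self.n_excluded_by_rule.values())


def filter_cohort(df: pd.DataFrame) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Apply entry criteria; every input record is accounted for exactly once."""
    report = CohortFilterReport(n_input=len(df))
    keep = np.ones(len(df), dtype=bool)
    for name, rule in FILTER_RULES:
        fails = rule(df).to_numpy(dtype=bool) & keep
        report.n_excluded_by_rule[name] = int(fails.sum())
        keep &= ~fails
    out = df.loc[keep].copy()
    report.n_output = len(out)
    report.validate()
    return out, report


def _regression_impute(df: pd.DataFrame, target: str, predictors: list[str]) -> pd.Series:
    obs = df[target].notna()
    if not obs.any():
        raise ImputationError(f"all values of {target!r} are missing; cannot impute")
    if obs.all():
        return df[target]
    X = build_design_matrix(df, predictors)
    X.insert(0, "_intercept", 1.0)
    beta, *_ = np.linalg.lstsq(X.loc[obs].to_numpy(dtype=float),
                               df.loc[obs, target].to_numpy(dtype=float), rcond=None)
    filled = df[target].copy()
    filled[~obs] = X.loc[~obs].to_numpy(dtype=float) @ beta
    return filled


def impute_missing(df: pd.DataFrame) -> pd.DataFrame:
    """Fill BMI, cold ischemia time, and length of stay; observed values untouched."""
    out = df.copy()
    out["bmi"] = _regression_impute(
        out, "bmi", ["recipient_age", "recipient_female", "race_ethnicity"])
    out["cit_hours"] = _regression_impute(
        out, "cit_hours", ["sharing", "distance_miles"])
    los_obs = out["los_days"].dropna()
    if los_obs.empty:
        raise ImputationError("all values of 'los_days' are missing; cannot impute")
    out["los_days"] = out["los_days"].fillna(float(los_obs.median()))
    return out


@dataclass
class GroupComparison:
    """One variable compared between the dual and single groups."""

    variable: str
    kind: str  # 'continuous' | 'categorical'
    statistic: float
    p_value: float
    summary: dict  # group -> "median (Q1, Q3)" or level -> "n (%)"
    degenerate: bool = False


def _continuous_summary(x: pd.Series) -> str:
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def compare_groups(df: pd.DataFrame, variable: str,
                   kind: str | None = None, group_col: str = "group") -> GroupComparison:
    """Wilcoxon rank-sum (tie-corrected normal approximation) for continuous
    variables; Pearson chi-square without continuity correction for
    categorical variables. Binary/flag variables are treated as categorical.
    """
    groups = [g for g in ("dual", "single") if (df[group_col] == g).any()]
    if len(groups) < 2:
        raise ValueError("both groups must be present")
    s = df[variable]
    if kind is None:
        kind = ("categorical" if is_categorical(s) or s.dtype == bool
                or s.dropna().isin([0, 1]).all() else "continuous")

    a = df.loc[df[group_col] == "dual", variable].dropna()
    b = df.loc[df[group_col] == "single", variable].dropna()

    if kind == "continuous":
        if s.dropna().nunique() <= 1:
            return GroupComparison(variable, kind, 0.0, float("nan"),
                                   {"dual": _continuous_summary(a),
                                    "single": _continuous_summary(b)}, degenerate=True)
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        return GroupComparison(variable, kind, float(res.statistic), float(res.pvalue),
                               {"dual": _continuous_summary(a),
                                "single": _continuous_summary(b)})

    table = pd.crosstab(df[group_col], s)
    summary = {}
    for g in ("dual", "single"):
        counts = table.loc[g] if g in table.index else None
        if counts is not None:
            total = counts.sum()
            summary[g] = {str(lev): f"{int(c)} ({100 * c / total:.1f}%)"
                          for lev, c in counts.items()}
    if table.shape[1] <= 1:
        return GroupComparison(variable, "categorical", 0.0, float("nan"),
                               summary, degenerate=True)
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return GroupComparison(variable, "categorical", float(chi2), float(p), summary)


def comparison_from_counts(variable: str, dual: tuple[int, int],
                           single: tuple[int, int]) -> GroupComparison:
    """Chi-square comparison of a binary outcome given (events, n) per group."""
    rows = []
    for g, (k, n) in (("dual", dual), ("single", single)):
        rows.append(pd.DataFrame({"group": g, variable: [True] * k + [False] * (n - k)}))
    return compare_groups(pd.concat(rows, ignore_index=True), variable, kind="categorical")


def proportion(events: int, n: int) -> float:
    """Event proportion in percent, as printed in outcome tables."""
    return 100.0 * events / n


def demographic_table(df: pd.DataFrame, variables: list[str],
                      group_col: str = "group") -> pd.DataFrame:
    """Descriptive comparison table: median (IQR) / n (%) per group plus p-value."""
    rows = []
    for var in variables:
        cmp = compare_groups(df, var, group_col=group_col)
        if cmp.kind == "continuous":
            rows.append({"variable": var, "level": "", "dual": cmp.summary["dual"],
                         "single": cmp.summary["single"], "p_value": cmp.p_value})
        else:
            first = True
            for lev in sorted(set(cmp.summary.get("dual", {}))
                              | set(cmp.summary.get("single", {}))):
                rows.append({
                    "variable": var, "level": lev,
                    "dual": cmp.summary.get("dual", {}).get(lev, "0 (0.0%)"),
                    "single": cmp.summary.get("single", {}).get(lev, "0 (0.0%)"),
                    "p_value": cmp.p_value if first else np.nan,
                })
                first = False
    return pd.DataFrame(rows)
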