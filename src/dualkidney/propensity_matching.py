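"""Propensity-score estimation and greedy nearest-neighbour matching.

The propensity model is a maximum-likelihood logistic regression of group
membership (dual = 1) on the demographic covariates, fitted by iteratively
reweighted least squares. Matching is greedy k:1 nearest-neighbour without
replacement on the *logit* of the propensity score: treated units are
processed in descending propensity order (hardest to match first, seeded
random tie-break) and each takes its k nearest unused controls before the
next treated unit is considered. Balance is assessed with standardized mean
differences (SMD); the matching ratio is chosen as the largest candidate
ratio whose post-match balance keeps every |SMD| within the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._design import build_design_matrix, check_full_rank

#: default propensity covariates: the demographic-table variables carried by
#: the registry schema (donor, recipient, and transplant factors).
DEFAULT_PS_COVARIATES = [
    "donor_age", "kdri", "pump", "donor_female", "cit_hours",
    "glomerulosclerosis", "inotropic_support", "sharing", "distance_miles",
    "recipient_age", "epts", "dialysis_group", "pvd", "renal_diagnosis",
    "bmi", "cpra", "abo_incompatible", "hla_mismatch", "induction",
    "steroids_maintenance",
]


class SeparationError(RuntimeError):
    """Perfect separation: the likelihood has no finite maximizer."""


class MatchingError(RuntimeError):
    """Matching could not be completed under the requested policy."""


@dataclass
class PropensityModel:
    coefficients: dict
    intercept: float
    converged: bool
    n_iterations: int
    log_likelihood: float
    design_columns: list = field(default_factory=list)
    covariates: list = field(default_factory=list)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = build_design_matrix(df, self.covariates, columns=self.design_columns)
        beta = np.array([self.coefficients[c] for c in self.design_columns])
        return self.intercept + X.to_numpy(dtype=float) @ beta

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Propensity scores in (0,1)."""
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(df)))


def _separating_covariate(X: pd.DataFrame, y: np.ndarray) -> str | None:
    for col in X.columns:
        x1, x0 = X.loc[y == 1, col], X.loc[y == 0, col]
        if x1.min() > x0.max() or x0.min() > x1.max():
            return col
    return None


def fit_propensity(df: pd.DataFrame, covariates: list[str] | None = None,
                   group_col: str = "group", tol: float = 1e-10,
                   maxiter: int = 100) -> PropensityModel:
    """ML logistic regression of dual-group membership on ``covariates``."""
    covariates = list(covariates or DEFAULT_PS_COVARIATES)
    y = (df[group_col] == "dual").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both groups must be present to fit a propensity model")
    X = build_design_matrix(df, covariates)
    check_full_rank(X)
    culprit = _separating_covariate(X, y)
    if culprit is not None:
        raise SeparationError(f"perfect separation on covariate {culprit!r}")
    exog = sm.add_constant(X.to_numpy(dtype=float), prepend=True)
    model = sm.GLM(y, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=maxiter, tol=tol)
        except Exception as exc:  # IRLS blow-up (quasi-separation etc.)
            raise SeparationError("logistic fit did not converge") from exc
    params = np.asarray(res.params)
    if not np.isfinite(params).all() or np.abs(params).max() > 1e4:
        raise SeparationError("logistic fit diverged (quasi-separation)")
    history = getattr(res, "fit_history", None) or {}
    n_iter = int(history.get("iteration", maxiter))
    return PropensityModel(
        coefficients=dict(zip(X.columns, params[1:])),
        intercept=float(params[0]),
        converged=bool(getattr(res, "converged", True)),
        n_iterations=n_iter,
        log_likelihood=float(res.llf),
        design_columns=list(X.columns),
        covariates=covariates,
    )


@dataclass
class MatchedCohort:
    ratio: int
    pairs: dict  # treated id -> list of k control ids
    balance: dict = field(default_factory=dict)  # covariate -> post-match SMD
    n_treated: int = 0
    n_control: int = 0
    balanced: bool | None = None
    candidate_balance: dict = field(default_factory=dict)  # ratio -> max |SMD|

    @property
    def treated_ids(self) -> list:
        return list(self.pairs)

    @property
    def control_ids(self) -> list:
        return [c for ctrls in self.pairs.values() for c in ctrls]

    def matched_ids(self) -> list:
        return self.treated_ids + self.control_ids

    def subset(self, df: pd.DataFrame, id_col: str = "id") -> pd.DataFrame:
        return df[df[id_col].isin(set(self.matched_ids()))].copy()

    def pairs_frame(self) -> pd.DataFrame:
        rows = [(t, c, i) for t, ctrls in self.pairs.items()
                for i, c in enumerate(ctrls)]
        return pd.DataFrame(rows, columns=["treated_id", "control_id", "pair_index"])


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def nearest_neighbor_match(scores, treated_ids, control_ids,
                           ratio: int = 1, seed: int = 0,
                           strict: bool = True) -> MatchedCohort:
    """Greedy sequential k:1 matching without replacement on logit scores.

    ``scores`` maps every id (treated and control) to its propensity score.
    Exact distance ties are broken by a seeded random jitter far below any
    meaningful score difference; with ``strict`` the pool must hold
    ``ratio * len(treated_ids)`` controls.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    treated_ids = list(treated_ids)
    control_ids = list(control_ids)
    shortfall = ratio * len(treated_ids) - len(control_ids)
    if shortfall > 0 and strict:
        raise MatchingError(
            f"control pool short by {shortfall} for {ratio}:1 matching")
    rng = np.random.default_rng(seed)
    get = scores.get if isinstance(scores, dict) else lambda k: scores[k]
    t_logit = _logit([get(t) for t in treated_ids])
    c_logit = _logit([get(c) for c in control_ids])

    # process hardest-to-match (highest score) first; random tie-break
    t_order = np.lexsort((rng.random(len(treated_ids)), -t_logit))
    c_jitter = rng.random(len(control_ids)) * 1e-9
    available = np.ones(len(control_ids), dtype=bool)
    pairs: dict = {}
    for ti in t_order:
        tid = treated_ids[ti]
        k = min(ratio, int(available.sum()))
        if k == 0:
            pairs[tid] = []
            continue
        d = np.abs(c_logit - t_logit[ti]) + c_jitter
        d[~available] = np.inf
        chosen = np.argpartition(d, k - 1)[:k]
        chosen = chosen[np.argsort(d[chosen])]
        available[chosen] = False
        pairs[tid] = [control_ids[j] for j in chosen]
    n_control = sum(len(v) for v in pairs.values())
    return MatchedCohort(ratio=ratio, pairs=pairs,
                         n_treated=len(treated_ids), n_control=n_control)


def standardized_mean_difference(values_a, values_b, kind: str = "continuous") -> float:
    """SMD between two samples; ``kind`` is 'continuous' or 'binary'.

    Zero pooled variance with unequal means yields +/- inf (degenerate flag).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if kind == "binary":
        pa, pb = a.mean(), b.mean()
        pooled = (pa * (1 - pa) + pb * (1 - pb)) / 2.0
        diff = pa - pb
    else:
        va = a.var(ddof=1) if a.size > 1 else 0.0
        vb = b.var(ddof=1) if b.size > 1 else 0.0
        pooled = (va + vb) / 2.0
        diff = a.mean() - b.mean()
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled))


def covariate_smd(df: pd.DataFrame, covariate: str, group_col: str = "group") -> float:
    """SMD for one covariate; multi-level categoricals report the max
    absolute per-level binary SMD (sign kept from the extreme level)."""
    a = df.loc[df[group_col] == "dual", covariate]
    b = df.loc[df[group_col] == "single", covariate]
    s = df[covariate]
    if s.dtype == bool:
        return standardized_mean_difference(a.astype(float), b.astype(float), "binary")
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        levels = (s.cat.categories if isinstance(s.dtype, pd.CategoricalDtype)
                  else sorted(pd.unique(s.dropna())))
        smds = [standardized_mean_difference((a == lev).astype(float),
                                             (b == lev).astype(float), "binary")
                for lev in levels]
        return max(smds, key=abs)
    return standardized_mean_difference(a.dropna(), b.dropna(), "continuous")


def balance_table(df: pd.DataFrame, cohort: MatchedCohort,
                  covariates: list[str], id_col: str = "id") -> pd.DataFrame:
    """Love-plot-ready table of SMDs before and after matching."""
    matched = cohort.subset(df, id_col=id_col)
    rows = []
    for cov in covariates:
        rows.append({"covariate": cov,
                     "smd_before": covariate_smd(df, cov),
                     "smd_after": covariate_smd(matched, cov)})
    return pd.DataFrame(rows)


def select_matching_ratio(df: pd.DataFrame, covariates: list[str] | None = None,
                          ratios=(1, 2, 3), threshold: float = 0.1,
                          seed: int = 0, id_col: str = "id",
                          group_col: str = "group",
                          model: PropensityModel | None = None) -> MatchedCohort:
    """Evaluate candidate ratios; return the largest whose post-match
    max |SMD| stays within ``threshold`` (best-balanced with
    ``balanced=False`` if none qualifies)."""
    if not ratios:
        raise ValueError("ratios must be nonempty")
    covariates = list(covariates or DEFAULT_PS_COVARIATES)
    if model is None:
        model = fit_propensity(df, covariates, group_col=group_col)
    scores = dict(zip(df[id_col], model.predict(df)))
    treated = df.loc[df[group_col] == "dual", id_col].tolist()
    controls = df.loc[df[group_col] == "single", id_col].tolist()

    candidates: dict[int, MatchedCohort] = {}
    max_smd: dict[int, float] = {}
    for r in ratios:
        cohort = nearest_neighbor_match(scores, treated, controls, ratio=r,
                                        seed=seed, strict=False)
        tab = balance_table(df, cohort, covariates, id_col=id_col)
        cohort.balance = dict(zip(tab["covariate"], tab["smd_after"]))
        max_smd[r] = float(tab["smd_after"].abs().max())
        candidates[r] = cohort

    passing = [r for r in ratios if max_smd[r] <= threshold]
    if passing:
        chosen = candidates[max(passing)]
        chosen.balanced = True
    else:
        chosen = candidates[min(max_smd, key=max_smd.get)]
        chosen.balanced = False
    chosen.candidate_balance = max_smd
    return chosen
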