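"""Propensity model, greedy matching vs brute-force oracle, and SMD balance."""

import math

import numpy as np
import pandas as pd
import pytest

from dualkidney.propensity_matching import (
    MatchingError, SeparationError, covariate_smd, fit_propensity,
    nearest_neighbor_match, select_matching_ratio,
    standardized_mean_difference, _logit,
)
from dualkidney.synthetic_registry import GeneratorConfig, generate_registry

from conftest import make_records


def _two_by_two_frame(n11, n10, n01, n00):
    """dual: n11 exposed / n10 unexposed; single: n01 exposed / n00 unexposed."""
    group = ["dual"] * (n11 + n10) + ["single"] * (n01 + n00)
    x = [1.0] * n11 + [0.0] * n10 + [1.0] * n01 + [0.0] * n00
    df = make_records(group=group)
    df["x"] = x
    return df


def test_logistic_fit_reproduces_2x2_log_odds_ratio():
    """Coefficient equals log((10*120)/(20*30)) = log 2 to 1e-8."""
    df = _two_by_two_frame(10, 20, 30, 120)
    model = fit_propensity(df, ["x"])
    assert model.coefficients["x"] == pytest.approx(math.log(2.0), abs=1e-8)


def test_null_covariate_gives_prevalence_scores():
    rng = np.random.default_rng(4)
    df = make_records(group=["dual"] * 50 + ["single"] * 150)
    df["x"] = rng.normal(size=200)  # same distribution in both groups
    model = fit_propensity(df, ["x"])
    assert abs(model.coefficients["x"]) < 0.5
    ps = model.predict(df)
    assert np.allclose(ps.mean(), 0.25, atol=0.02)


def test_score_equation_holds_at_solution():
    """Gradient of the log-likelihood at the fit is numerically zero."""
    df = generate_registry(GeneratorConfig(n_dual=150, n_single=600, seed=6))
    covs = ["donor_age", "kdri", "recipient_age", "pump"]
    model = fit_propensity(df, covs)
    y = (df["group"] == "dual").to_numpy(float)
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in covs])
    beta = np.r_[model.intercept, [model.coefficients[c] for c in covs]]
    p = 1 / (1 + np.exp(-X @ beta))
    grad = X.T @ (y - p)
    # scale-free criterion: gradient relative to column scale
    assert np.max(np.abs(grad) / np.maximum(np.abs(X).sum(axis=0), 1.0)) < 1e-6


def test_perfect_separation_raises_naming_covariate():
    df = make_records(group=["dual"] * 5 + ["single"] * 5)
    df["x"] = [1.0] * 5 + [0.0] * 5
    with pytest.raises(SeparationError, match="x"):
        fit_propensity(df, ["x"])


def test_collinear_design_raises_rank_error():
    df = make_records(group=["dual"] * 10 + ["single"] * 10)
    rng = np.random.default_rng(0)
    df["x"] = rng.normal(size=20)
    df["x2"] = 2.0 * df["x"]
    with pytest.raises(np.linalg.LinAlgError):
        fit_propensity(df, ["x", "x2"])


# --- greedy nearest-neighbour matching --------------------------------------

def greedy_oracle(scores, treated_ids, control_ids, ratio):
    """Naive greedy matcher on logit distance: treated in descending score
    order, each takes its nearest unused controls by linear scan."""
    lg = {k: math.log(v / (1 - v)) for k, v in scores.items()}
    unused = set(control_ids)
    pairs = {}
    for t in sorted(treated_ids, key=lambda k: -scores[k]):
        chosen = sorted(unused, key=lambda c: abs(lg[c] - lg[t]))[:ratio]
        for c in chosen:
            unused.discard(c)
        pairs[t] = chosen
    return pairs


def test_greedy_matches_spec_toy():
    """2 treated (0.8, 0.2) vs 6 controls; on the logit scale 0.79 is the
    nearest control to 0.8 (verified by the brute-force oracle)."""
    scores = {"t1": 0.8, "t2": 0.2, "c1": 0.81, "c2": 0.79, "c3": 0.5,
              "c4": 0.22, "c5": 0.19, "c6": 0.05}
    controls = ["c1", "c2", "c3", "c4", "c5", "c6"]
    expected = greedy_oracle(scores, ["t1", "t2"], controls, 1)
    got = nearest_neighbor_match(scores, ["t1", "t2"], controls, ratio=1, seed=0)
    assert got.pairs == expected == {"t1": ["c2"], "t2": ["c5"]}


@pytest.mark.parametrize("ratio", [1, 2])
def test_greedy_equals_oracle_on_small_instances(ratio):
    """Implementation agrees with the naive greedy oracle on every random
    instance of <= 12 units (distinct scores)."""
    rng = np.random.default_rng(99)
    for _ in range(40):
        n_t = int(rng.integers(1, 5))
        n_c = int(rng.integers(ratio * n_t, 13 - n_t))
        vals = rng.uniform(0.02, 0.98, size=n_t + n_c)
        if len(np.unique(vals)) < len(vals):
            continue
        ids = [f"u{i}" for i in range(n_t + n_c)]
        scores = dict(zip(ids, vals))
        treated, controls = ids[:n_t], ids[n_t:]
        got = nearest_neighbor_match(scores, treated, controls, ratio=ratio, seed=1)
        assert got.pairs == greedy_oracle(scores, treated, controls, ratio)


def test_matching_without_replacement_no_duplicates():
    rng = np.random.default_rng(17)
    ids = [f"u{i}" for i in range(400)]
    scores = dict(zip(ids, rng.uniform(0.01, 0.99, 400)))
    for seed in range(5):
        mc = nearest_neighbor_match(scores, ids[:100], ids[100:], ratio=3, seed=seed)
        controls = mc.control_ids
        assert len(controls) == len(set(controls)) == 300
        assert mc.n_control == 3 * mc.n_treated


def test_three_to_one_ratio_yields_thrice_the_controls():
    rng = np.random.default_rng(23)
    n_t = 1015
    ids = [f"t{i}" for i in range(n_t)] + [f"c{i}" for i in range(4000)]
    scores = dict(zip(ids, rng.uniform(0.01, 0.99, len(ids))))
    mc = nearest_neighbor_match(scores, ids[:n_t], ids[n_t:], ratio=3, seed=0)
    assert mc.n_control == 3045


def test_tied_scores_matched_deterministically():
    scores = {k: 0.5 for k in ("t1", "t2", "c1", "c2", "c3", "c4")}
    runs = [nearest_neighbor_match(scores, ["t1", "t2"], ["c1", "c2", "c3", "c4"],
                                   ratio=1, seed=7).pairs for _ in range(3)]
    assert runs[0] == runs[1] == runs[2]


def test_exhausted_controls_raise_under_strict_policy():
    scores = {"t1": 0.5, "t2": 0.6, "c1": 0.5}
    with pytest.raises(MatchingError):
        nearest_neighbor_match(scores, ["t1", "t2"], ["c1"], ratio=1, seed=0)


# --- standardized mean differences -------------------------------------------

def test_smd_identical_samples_is_zero():
    assert standardized_mean_difference([1, 2, 3], [1, 2, 3]) == 0.0


def test_smd_continuous_plug_in():
    rng = np.random.default_rng(0)
    a = rng.normal(1, 1, 200_000)
    b = rng.normal(0, 1, 200_000)
    assert standardized_mean_difference(a, b) == pytest.approx(1.0, abs=0.02)
    # exact check on constructed samples with unit variance and unit shift
    x = np.array([0.0, 2.0])  # mean 1, var 2
    y = np.array([-1.0, 1.0])  # mean 0, var 2
    assert standardized_mean_difference(x, y) == pytest.approx(1 / math.sqrt(2))


def test_smd_binary_plug_in():
    a = np.r_[np.ones(30), np.zeros(70)]
    b = np.r_[np.ones(20), np.zeros(80)]
    want = 0.1 / math.sqrt((0.3 * 0.7 + 0.2 * 0.8) / 2)
    got = standardized_mean_difference(a, b, kind="binary")
    assert got == pytest.approx(want) == pytest.approx(0.23250, abs=1e-4)


def test_smd_zero_variance_unequal_means_is_infinite():
    assert standardized_mean_difference([1.0, 1.0], [0.0, 0.0]) == math.inf


def test_categorical_smd_reports_extreme_level():
    df = make_records(group=["dual"] * 40 + ["single"] * 40)
    df["renal_diagnosis"] = ["diabetes"] * 30 + ["glomerular"] * 10 + \
        ["diabetes"] * 10 + ["glomerular"] * 30
    assert abs(covariate_smd(df, "renal_diagnosis")) > 0.5


# --- ratio selection ----------------------------------------------------------

def test_randomized_groups_select_largest_ratio():
    """With zero confounding every ratio balances (up to sampling noise well
    below the threshold at this size), so 3:1 is selected."""
    rng = np.random.default_rng(8)
    df = make_records(group=["dual"] * 1000 + ["single"] * 10000)
    df["x1"] = rng.normal(size=11000)
    cohort = select_matching_ratio(df, ["x1"], ratios=(1, 2, 3),
                                   threshold=0.1, seed=0)
    assert cohort.ratio == 3 and cohort.balanced


def test_unbalanceable_covariate_sets_flag():
    """A covariate with disjoint group supports cannot be balanced by any
    ratio; the best-balanced cohort is returned flagged."""
    rng = np.random.default_rng(9)
    df = make_records(group=["dual"] * 40 + ["single"] * 400)
    df["x1"] = rng.normal(size=440)
    df["x2"] = np.r_[rng.normal(10, 0.1, 40), rng.normal(0, 0.1, 400)]
    model = fit_propensity(df, ["x1"])  # x2 deliberately outside the model
    cohort = select_matching_ratio(df, ["x1", "x2"], ratios=(1, 2),
                                   threshold=0.1, seed=0, model=model)
    assert cohort.balanced is False
    assert abs(cohort.balance["x2"]) > 1.0


def test_matching_reduces_imbalance_on_confounded_cohorts():
    """Across 20 seeds the mean post-match |SMD| over covariates is below the
    pre-match value."""
    from dualkidney.cohort_pipeline import impute_missing
    from dualkidney.propensity_matching import balance_table
    covs = ["donor_age", "kdri", "recipient_age", "epts", "cit_hours"]
    better = 0
    for seed in range(20):
        df = impute_missing(
            generate_registry(GeneratorConfig(n_dual=60, n_single=1200, seed=seed)))
        model = fit_propensity(df, covs)
        scores = dict(zip(df["id"], model.predict(df)))
        mc = nearest_neighbor_match(scores, df.loc[df.group == "dual", "id"].tolist(),
                                    df.loc[df.group == "single", "id"].tolist(),
                                    ratio=1, seed=seed)
        tab = balance_table(df, mc, covs)
        if tab["smd_after"].abs().mean() < tab["smd_before"].abs().mean():
            better += 1
    assert better >= 18
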