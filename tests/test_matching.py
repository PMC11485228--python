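"""Propensity model, greedy caliper matching, SMD and CEM."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from natexp import (
    CoarseningSpec,
    balance_table,
    coarsened_exact_match,
    fit_propensity,
    match_nearest,
    standardized_mean_difference,
)
from natexp.matching import build_design
from natexp.pipeline import default_covariates


# -- standardized mean difference -------------------------------------

@pytest.mark.parametrize(
    "a, b, kind, expected",
    [
        ([1, 1, 0, 0, 0] * 2, [1, 1, 0, 0, 0] * 2, "binary", 0.0),
        ([1] * 5 + [0] * 5, [1] * 3 + [0] * 7, "binary", 0.2 / np.sqrt(0.23)),
        ([2.0, 2.0, 2.0], [2.0, 2.0], "continuous", 0.0),  # degenerate, equal
    ],
)
def test_smd_known_values(a, b, kind, expected):
    assert standardized_mean_difference(a, b, kind) == pytest.approx(expected, abs=1e-12)


def test_smd_zero_variance_unequal_means_is_infinite():
    assert standardized_mean_difference([1.0, 1.0], [2.0, 2.0], "continuous") == np.inf


def test_smd_continuous_matches_independent_formula():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.normal(rng.normal(), rng.uniform(0.5, 2), 40)
        b = rng.normal(rng.normal(), rng.uniform(0.5, 2), 55)
        expected = abs(a.mean() - b.mean()) / np.sqrt(
            (a.var(ddof=1) + b.var(ddof=1)) / 2
        )
        assert standardized_mean_difference(a, b, "continuous") == pytest.approx(expected)


# -- propensity model --------------------------------------------------

def toy_table(n=40, informative=False, seed=0):
    rng = np.random.default_rng(seed)
    era = np.array(["comparator", "primary"])[rng.integers(0, 2, n)]
    p = np.where(era == "primary", 0.7 if informative else 0.4, 0.4)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "era": era,
            "x": (rng.random(n) < p).astype(int),
        }
    )


def test_uninformative_covariates_give_constant_scores():
    df = toy_table(400, informative=False, seed=1)
    model = fit_propensity(df, ["x"])
    frac = (df["era"] == "primary").mean()
    assert np.allclose(model.scores, frac, atol=0.06)


def test_coefficient_sign_follows_prevalence_direction():
    df = toy_table(800, informative=True, seed=2)
    model = fit_propensity(df, ["x"])
    assert model.coefficients["x"] > 0


def test_scores_match_independent_mle_on_fixture():
    # 8-patient constructed fixture, oracle = generic likelihood optimizer
    df = pd.DataFrame(
        {
            "patient_id": list("abcdefgh"),
            "era": ["comparator"] * 4 + ["primary"] * 4,
            "x": [0, 0, 1, 1, 0, 1, 1, 1],
        }
    )
    model = fit_propensity(df, ["x"])
    y = (df["era"] == "primary").to_numpy(float)
    x = df["x"].to_numpy(float)

    def nll(b):
        lin = b[0] + b[1] * x
        return -np.sum(y * lin - np.logaddexp(0, lin))

    res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14})
    oracle = 1 / (1 + np.exp(-(res.x[0] + res.x[1] * x)))
    assert np.allclose(model.scores.to_numpy(), oracle, atol=1e-6)


def test_design_firewalls_outcome_columns(paper_like_cohort):
    with pytest.raises(ValueError, match="outcome columns"):
        build_design(paper_like_cohort, ["dementia_time"])


# -- greedy caliper matching -------------------------------------------

def make_scores(comp_scores, prim_scores):
    n_c, n_p = len(comp_scores), len(prim_scores)
    ids = [f"c{i}" for i in range(n_c)] + [f"p{i}" for i in range(n_p)]
    era = pd.Series(["comparator"] * n_c + ["primary"] * n_p, index=ids)
    scores = pd.Series(list(comp_scores) + list(prim_scores), index=ids)
    return era, scores


def test_identical_score_multisets_fully_matched():
    vals = [0.1, 0.25, 0.4, 0.4, 0.7]
    era, scores = make_scores(vals, vals)
    m = match_nearest(era, scores, caliper=0.1, seed=3)
    assert m.n_pairs == 5
    diffs = np.abs(m.pairs["ps_a"] - m.pairs["ps_b"])
    assert np.allclose(diffs, 0.0)


def test_zero_caliper_distinct_scores_no_pairs():
    era, scores = make_scores([0.2, 0.4], [0.3, 0.5])
    m = match_nearest(era, scores, caliper=0.0, seed=0)
    assert m.n_pairs == 0
    assert len(m.unmatched) == 4


def test_greedy_no_worse_than_half_of_optimal_and_within_caliper():
    # brute-force maximum bipartite matching under the caliper as oracle
    import networkx as nx

    rng = np.random.default_rng(8)
    comp = rng.random(10)
    prim = rng.random(10)
    caliper = 0.08
    era, scores = make_scores(comp, prim)
    m = match_nearest(era, scores, caliper=caliper, seed=1)
    assert (np.abs(m.pairs["ps_a"] - m.pairs["ps_b"]) <= caliper + 1e-12).all()

    G = nx.Graph()
    left = [f"c{i}" for i in range(10)]
    right = [f"p{j}" for j in range(10)]
    G.add_nodes_from(left, bipartite=0)
    G.add_nodes_from(right, bipartite=1)
    for i, a in enumerate(comp):
        for j, b in enumerate(prim):
            if abs(a - b) <= caliper:
                G.add_edge(f"c{i}", f"p{j}")
    opt = len(nx.algorithms.matching.max_weight_matching(G, maxcardinality=True))
    assert m.n_pairs <= opt
    # greedy maximal matching is at least half the optimum
    assert m.n_pairs >= opt / 2


def test_matching_determinism_and_seed_dependence():
    rng = np.random.default_rng(5)
    era, scores = make_scores(rng.random(50), rng.random(60))
    m1 = match_nearest(era, scores, 0.1, seed=7)
    m2 = match_nearest(era, scores, 0.1, seed=7)
    pd.testing.assert_frame_equal(m1.pairs, m2.pairs)


def test_ps_matching_balances_drifted_cohort(paper_like_cohort):
    df = paper_like_cohort
    covs = default_covariates(df)
    model = fit_propensity(df, covs)
    era = pd.Series(df["era"].to_numpy(), index=df["patient_id"].to_numpy())
    m = match_nearest(era, model.scores, 0.1, seed=2)
    bt = balance_table(df, covs, m)
    assert (bt["smd_before"] > 0.15).sum() >= 3  # drift is real pre-match
    assert bt["smd_after"].max() < 0.1           # and removed post-match


# -- coarsened exact matching ------------------------------------------

def cem_table(comp_sig, prim_sig):
    n_c, n_p = len(comp_sig), len(prim_sig)
    return pd.DataFrame(
        {
            "patient_id": [f"c{i}" for i in range(n_c)] + [f"p{i}" for i in range(n_p)],
            "era": ["comparator"] * n_c + ["primary"] * n_p,
            "grp": list(comp_sig) + list(prim_sig),
        }
    )


def test_cem_single_stratum_pair_count():
    df = cem_table(["a"] * 3, ["a"] * 5)
    m = coarsened_exact_match(df, CoarseningSpec(variables=("grp",)), seed=0)
    assert m.n_pairs == 3
    assert (m.pairs["stratum"] == "a").all()


def test_cem_disjoint_signatures_no_pairs():
    df = cem_table(["a", "b"], ["c", "d"])
    m = coarsened_exact_match(df, CoarseningSpec(variables=("grp",)), seed=0)
    assert m.n_pairs == 0


def test_cem_stratum_set_is_seed_invariant(paper_like_cohort):
    spec = CoarseningSpec(variables=("age_years", "sex", "comorb_00"))
    m1 = coarsened_exact_match(paper_like_cohort, spec, seed=1)
    m2 = coarsened_exact_match(paper_like_cohort, spec, seed=99)
    assert set(m1.pairs["stratum"]) == set(m2.pairs["stratum"])
    assert m1.n_pairs == m2.n_pairs


def test_cem_never_increases_smd_on_coarsened_variables(paper_like_cohort):
    df = paper_like_cohort
    covs = ("age_years", "sex", "race", "comorb_00", "comorb_07")
    m = coarsened_exact_match(df, CoarseningSpec(variables=covs), seed=4)
    bt = balance_table(df, covs, m)
    assert (bt["smd_after"] <= bt["smd_before"] + 1e-9).all()
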