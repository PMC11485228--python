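"""KM estimation, RMTL inference and the classical two-group tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from natexp import (
    HorizonError,
    RmtlEstimate,
    cox_fit,
    km_fit,
    km_rmtl,
    logrank_test,
    ph_test,
    rmtl,
    rmtl_compare,
)
from tests.conftest import exp_sample


# -- Kaplan–Meier -------------------------------------------------------

def test_km_product_limit_by_hand():
    c = km_fit([1, 2, 3], [1, 1, 1])
    assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])
    assert np.array_equal(c.n_risk, [3, 2, 1])


def test_km_single_censored_subject_keeps_s_at_one():
    c = km_fit([5.0], [0])
    assert c.survival[0] == 1.0
    assert c.greenwood_var[0] == 0.0


def test_km_matches_lifelines_with_ties_and_censoring():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(2)
    t = np.round(rng.exponential(2, 400), 1) + 0.1  # force ties
    c = rng.uniform(0, 5, 400)
    obs = np.minimum(t, c)
    e = (t <= c).astype(int)
    ours = km_fit(obs, e)
    kmf = KaplanMeierFitter().fit(obs, e)
    theirs = kmf.survival_function_at_times(ours.times).to_numpy()
    assert np.allclose(ours.survival, theirs, atol=1e-12)


def test_greenwood_bands_cover_truth():
    # exponential(0.5), n=500, no censoring: 95% pointwise bands should
    # cover e^{-0.5 t} on >= 90% of grid points
    rng = np.random.default_rng(7)
    t, e = exp_sample(rng, 500, 0.5)
    c = km_fit(t, e)
    grid = np.linspace(0.2, 4.0, 60)
    idx = np.searchsorted(c.times, grid, side="right") - 1
    ok = idx >= 0
    s = c.survival[idx[ok]]
    se = np.sqrt(c.greenwood_var[idx[ok]])
    truth = np.exp(-0.5 * grid[ok])
    covered = (truth >= s - 1.96 * se) & (truth <= s + 1.96 * se)
    assert covered.mean() >= 0.90
    assert np.max(np.abs(s - truth)) < 0.08


def test_km_row_order_invariance():
    rng = np.random.default_rng(0)
    t, e = exp_sample(rng, 200, 0.4, cens=3.0)
    perm = rng.permutation(200)
    a, b = km_fit(t, e), km_fit(t[perm], e[perm])
    assert np.array_equal(a.times, b.times)
    assert np.allclose(a.survival, b.survival)


# -- RMTL ---------------------------------------------------------------

def test_rmtl_rectangle_integral():
    est = rmtl(km_fit([1.0] * 4, [1] * 4), tau=2.0)
    assert est.rmst == pytest.approx(1.0)
    assert est.rmtl == pytest.approx(1.0)


def test_rmtl_no_events_is_zero_with_zero_variance():
    est = rmtl(km_fit([2.0, 3.0, 4.0], [0, 0, 0]), tau=3.5)
    assert est.rmtl == 0.0
    assert est.variance == 0.0
    assert est.cumulative_incidence_at_tau == 0.0


def test_rmtl_tau_beyond_support_raises():
    with pytest.raises(HorizonError):
        rmtl(km_fit([2.0, 3.0], [1, 0]), tau=5.0)


def test_rmst_plus_rmtl_equals_tau_exactly():
    rng = np.random.default_rng(4)
    for _ in range(25):
        n = rng.integers(5, 200)
        t, e = exp_sample(rng, n, rng.uniform(0.1, 1.0), cens=rng.uniform(2, 8))
        tau = min(rng.uniform(0.5, 6.0), t.max())
        est = km_rmtl(t, e, tau)
        assert est.rmst + est.rmtl == pytest.approx(tau, abs=1e-12)


try:
    from hypothesis import given, settings, strategies as st

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.01, 10.0), st.integers(0, 1)),
            min_size=1, max_size=60,
        ),
        tau_frac=st.floats(0.05, 1.0),
    )
    def test_km_invariants_hold_for_arbitrary_samples(data, tau_frac):
        t = np.array([d[0] for d in data])
        e = np.array([d[1] for d in data])
        c = km_fit(t, e)
        assert np.all(np.diff(c.survival) <= 1e-12)      # S non-increasing
        assert np.all(c.survival <= 1.0) and np.all(c.greenwood_var >= 0)
        assert np.all(np.diff(c.n_risk) <= 0)
        tau = max(tau_frac * float(t.max()), 1e-6)
        est = rmtl(c, tau)
        assert 0.0 <= est.rmtl <= tau + 1e-12
        assert est.rmst + est.rmtl == pytest.approx(tau, abs=1e-12)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_rmst_matches_lifelines_oracle():
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    rng = np.random.default_rng(11)
    t, e = exp_sample(rng, 800, 0.3, cens=rng.uniform(1, 7, 800))
    tau = 4.0
    ours = km_rmtl(t, e, tau)
    kmf = KaplanMeierFitter().fit(t, e)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        theirs = restricted_mean_survival_time(kmf, t=tau)
    assert ours.rmst == pytest.approx(float(theirs), abs=1e-9)


def test_rmst_closed_form_and_variance_calibration():
    # exponential(0.2), tau=6: RMST -> (1-e^{-1.2})/0.2; parametric
    # variance consistent with the spread over replicates
    rng = np.random.default_rng(21)
    truth = (1 - np.exp(-1.2)) / 0.2
    reps = 120
    ests, vars_ = np.empty(reps), np.empty(reps)
    for i in range(reps):
        t, e = exp_sample(rng, 1000, 0.2, cens=6.0)
        r = km_rmtl(t, e, 6.0)
        ests[i], vars_[i] = r.rmst, r.variance
    se_mc = ests.std(ddof=1) / np.sqrt(reps)
    assert abs(ests.mean() - truth) < 3 * se_mc + 0.01
    assert vars_.mean() == pytest.approx(ests.var(ddof=1), rel=0.3)


def make_est(rmtl_v, var, tau=6.0, ci=0.1, ci_var=0.0):
    return RmtlEstimate(tau=tau, rmtl=rmtl_v, variance=var,
                        cumulative_incidence_at_tau=ci,
                        cumulative_incidence_var=ci_var, n=100)


def test_rmtl_compare_identical_groups():
    cmp_ = rmtl_compare(make_est(0.3, 0.001), make_est(0.3, 0.001))
    assert cmp_.ratio == pytest.approx(1.0)
    assert cmp_.additional_days == pytest.approx(0.0)
    assert cmp_.ci[0] < 1.0 < cmp_.ci[1]


def test_rmtl_compare_halved_rmtl_gives_ratio_half():
    cmp_ = rmtl_compare(make_est(0.2, 0.001), make_est(0.4, 0.001))
    assert cmp_.ratio == pytest.approx(0.5)
    # additional days: (0.4 - 0.2)/0.1 * 365.25
    assert cmp_.additional_days == pytest.approx(2.0 * 365.25)


def test_rmtl_compare_zero_rmtl_flags_degenerate():
    cmp_ = rmtl_compare(make_est(0.0, 0.0), make_est(0.4, 0.001))
    assert cmp_.degenerate
    assert np.isnan(cmp_.ratio)
    assert cmp_.rmtl_difference == pytest.approx(0.4)


# -- Cox / log-rank / PH ------------------------------------------------

def test_cox_fixture_matches_grid_search():
    # 6 subjects; oracle = direct maximization of the Breslow partial
    # likelihood on a fine grid
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    e = np.array([1, 1, 0, 1, 1, 0])
    g = np.array([1, 0, 1, 0, 1, 0])

    def neg_pl(beta):
        ll = 0.0
        for i in range(6):
            if e[i]:
                risk = t >= t[i]
                ll += beta * g[i] - np.log(np.sum(np.exp(beta * g[risk])))
        return -ll

    grid = np.linspace(-4, 4, 160001)
    oracle = grid[np.argmin([neg_pl(b) for b in grid])]
    log_hr, se, p = cox_fit(t, e, g)
    assert log_hr == pytest.approx(oracle, abs=1e-4)


def test_cox_recovers_true_hazard_ratio():
    rng = np.random.default_rng(9)
    n = 5000
    g = (rng.random(n) < 0.5).astype(int)
    t = rng.exponential(1 / (0.3 * np.exp(np.log(0.7) * g)))
    c = rng.uniform(1, 6, n)
    obs, e = np.minimum(t, c), (t <= c).astype(int)
    log_hr, se, p = cox_fit(obs, e, g)
    assert abs(log_hr - np.log(0.7)) < 3 * se


def test_cox_null_permutation_is_centered():
    rng = np.random.default_rng(3)
    t, e = exp_sample(rng, 400, 0.5, cens=4.0)
    hrs = []
    for _ in range(15):
        g = rng.permutation(np.repeat([0, 1], 200))
        log_hr, se, _ = cox_fit(t, e, g)
        hrs.append(log_hr / se)
    assert abs(np.mean(hrs)) < 0.8  # standardized, mean ~ 0


def test_cox_monotone_likelihood_flagged():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 1, 0, 0])
    g = np.array([0, 0, 1, 1])  # no events in group 1
    with pytest.warns(UserWarning, match="monotone"):
        log_hr, se, p = cox_fit(t, e, g)
    assert abs(log_hr) == 10.0


def test_logrank_and_ph_contract(paper_like_cohort):
    df = paper_like_cohort
    g = (df["era"] == "primary").to_numpy(int)
    t = df["dementia_time"].to_numpy()
    e = df["dementia_event"].to_numpy()
    for transform in ("km", "identity"):
        p = ph_test(t, e, g, time_transform=transform)
        assert 0.0 <= p <= 1.0
    assert 0.0 <= logrank_test(t, e, g) <= 1.0


def test_ph_test_requires_events():
    with pytest.raises(ValueError):
        ph_test([1.0, 2.0], [0, 1], [0, 1])
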