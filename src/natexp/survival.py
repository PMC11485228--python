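"""Kaplan–Meier estimation and restricted-mean time-lost (RMTL) inference.

The primary effect measure is the ratio of restricted mean time lost,
RMTL = τ − RMST with RMST = ∫₀^τ S(t) dt, between the two matched
cohorts.  The KM/RMST machinery is implemented directly on numpy arrays
because it sits inside permutation and bootstrap loops; the variance is
the standard large-sample RMST formula

    var(RMST) = Σ_{t_i ≤ τ} [∫_{t_i}^τ S du]² · d_i / (n_i (n_i − d_i))

summed over distinct event times.  Cox regression (Breslow ties),
the log-rank test and the generalized Schoenfeld proportional-hazards
test are delegated to statsmodels and lifelines.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_YEAR = 365.25


class HorizonError(ValueError):
    """Horizon τ lies beyond the observed follow-up; align horizons first."""


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with per-step counts and Greenwood variance."""

    times: np.ndarray       # distinct observed times, ascending
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censor: np.ndarray
    survival: np.ndarray    # S(t) just after each time
    greenwood_var: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """Left-continuous-step evaluation: S at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def max_time(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0


@dataclass(frozen=True)
class RmtlEstimate:
    tau: float
    rmtl: float
    variance: float
    cumulative_incidence_at_tau: float
    cumulative_incidence_var: float
    n: int

    @property
    def rmst(self) -> float:
        return self.tau - self.rmtl


@dataclass(frozen=True)
class RmtlComparison:
    rmtl_primary: RmtlEstimate
    rmtl_comparator: RmtlEstimate
    ratio: float
    ci: tuple[float, float]
    p_value: float
    additional_days: float
    additional_days_ci: tuple[float, float]
    degenerate: bool = False  # a zero RMTL made the ratio undefined

    @property
    def rmtl_difference(self) -> float:
        return self.rmtl_comparator.rmtl - self.rmtl_primary.rmtl


def km_fit(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate.

    At tied timestamps events are counted before censorings (both are
    simply tallied at the same distinct time, with the at-risk set
    containing everyone whose time is ≥ that time).  All-censored input
    yields the valid curve S ≡ 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if len(t) == 0:
        raise ValueError("empty input")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ut, first = np.unique(t, return_index=True)
    edges = np.append(first, len(t))
    d = np.add.reduceat(e, first)
    at_time = np.diff(edges)
    c = at_time - d
    n_risk = len(t) - first
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / n_risk
        surv = np.cumprod(frac)
        gw_term = np.where(n_risk > d, d / (n_risk * (n_risk - d).astype(float)), 0.0)
    gw = surv**2 * np.cumsum(gw_term)
    gw = np.where(surv > 0, gw, 0.0)
    return SurvivalCurve(
        times=ut, n_risk=n_risk, n_event=d, n_censor=c,
        survival=surv, greenwood_var=gw, n_total=len(t),
    )


def rmtl(curve: SurvivalCurve, tau: float) -> RmtlEstimate:
    """Restricted mean time lost over [0, τ] with its large-sample variance.

    Requires τ ≤ the largest observed time, since the KM estimate has no
    support beyond it.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tau > curve.max_time() + 1e-12 and curve.survival[-1] > 0:
        # beyond the last observed time the KM estimate has support only
        # if the curve has already dropped to zero
        raise HorizonError(
            f"tau={tau} exceeds the last observed time {curve.max_time():.6g}; "
            "restrict tau or align follow-up horizons"
        )
    k = int(np.searchsorted(curve.times, tau, side="left"))
    # step times within [0, tau) plus tau as the right edge
    seg_t = np.concatenate([[0.0], curve.times[:k], [tau]])
    seg_s = np.concatenate([[1.0], curve.survival[:k]])
    widths = np.diff(seg_t)
    rmst = float(np.sum(seg_s * widths))
    # variance: events strictly within (0, tau]
    m = int(np.searchsorted(curve.times, tau, side="right"))
    d = curve.n_event[:m]
    n = curve.n_risk[:m]
    # ∫_{t_i}^τ S du via reverse cumulative of segment areas
    areas_after = np.concatenate([np.cumsum((seg_s * widths)[::-1])[::-1][1:], [0.0]])
    # areas_after[j] = integral from curve.times[j] (j < k) to tau
    A = np.zeros(m)
    A[: min(m, k)] = areas_after[: min(m, k)]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((n > d) & (d > 0), A**2 * d / (n * (n - d).astype(float)), 0.0)
    var = float(np.sum(terms))
    s_tau = 1.0 if m == 0 else float(curve.survival[m - 1])
    s_var = 0.0 if m == 0 else float(curve.greenwood_var[m - 1])
    return RmtlEstimate(
        tau=float(tau), rmtl=float(tau - rmst), variance=var,
        cumulative_incidence_at_tau=1.0 - s_tau,
        cumulative_incidence_var=s_var, n=curve.n_total,
    )


def km_rmtl(times, events, tau: float) -> RmtlEstimate:
    """One-shot KM + RMTL, the fast path used by resampling loops."""
    return rmtl(km_fit(times, events), tau)


def rmtl_compare(
    primary: RmtlEstimate, comparator: RmtlEstimate, alpha: float = 0.05
) -> RmtlComparison:
    """Ratio of RMTL (primary / comparator) with delta-method CI and z-test,
    plus the additional-days translation ΔRMTL / cumulative incidence in the
    comparator cohort, reported in days.

    A zero RMTL in either group leaves the ratio undefined; the result is
    then flagged ``degenerate`` and carries the difference only.
    """
    if abs(primary.tau - comparator.tau) > 1e-9:
        raise ValueError("both estimates must share the same tau")
    z = stats.norm.ppf(1 - alpha / 2)
    diff = comparator.rmtl - primary.rmtl
    var_diff = primary.variance + comparator.variance

    if primary.rmtl <= 0 or comparator.rmtl <= 0:
        return RmtlComparison(
            rmtl_primary=primary, rmtl_comparator=comparator,
            ratio=np.nan, ci=(np.nan, np.nan), p_value=np.nan,
            additional_days=np.nan, additional_days_ci=(np.nan, np.nan),
            degenerate=True,
        )

    log_ratio = np.log(primary.rmtl) - np.log(comparator.rmtl)
    se_log = np.sqrt(
        primary.variance / primary.rmtl**2 + comparator.variance / comparator.rmtl**2
    )
    if se_log > 0:
        zstat = log_ratio / se_log
        p = 2 * stats.norm.sf(abs(zstat))
    else:
        p = 1.0 if log_ratio == 0 else 0.0
    ci = (float(np.exp(log_ratio - z * se_log)), float(np.exp(log_ratio + z * se_log)))

    # additional event-free days among those affected
    denom = comparator.cumulative_incidence_at_tau
    if denom > 0:
        ad = diff / denom
        var_ad = var_diff / denom**2 + diff**2 * comparator.cumulative_incidence_var / denom**4
        se_ad = np.sqrt(var_ad)
        ad_ci = ((ad - z * se_ad) * DAYS_PER_YEAR, (ad + z * se_ad) * DAYS_PER_YEAR)
        ad_days = ad * DAYS_PER_YEAR
    else:
        ad_days, ad_ci = np.nan, (np.nan, np.nan)
    return RmtlComparison(
        rmtl_primary=primary, rmtl_comparator=comparator,
        ratio=float(np.exp(log_ratio)), ci=ci, p_value=float(p),
        additional_days=float(ad_days),
        additional_days_ci=(float(ad_ci[0]), float(ad_ci[1])),
    )


# -- classical two-group machinery (delegated) -------------------------

def cox_fit(times, events, group):
    """Cox log hazard ratio (group=1 vs 0), Breslow tie handling.

    Returns (log_hr, se, wald_p).  Monotone likelihood (no events in one
    group) is flagged with a warning and a capped estimate.
    """
    import statsmodels.api as sm

    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group, int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group must be coded 0/1")
    ev_by_group = [e[g == v].sum() for v in (0, 1)]
    if min(ev_by_group) == 0:
        warnings.warn("no events in one group: monotone likelihood, capped estimate")
        cap = 10.0 * (1 if ev_by_group[0] > 0 else -1)
        return cap, np.inf, 1.0
    model = sm.PHReg(t, g[:, None], status=e, ties="breslow")
    res = model.fit(disp=False)
    log_hr = float(res.params[0])
    se = float(res.bse[0])
    if abs(log_hr) > 10:
        warnings.warn("near-monotone likelihood: estimate capped at |log HR| = 10")
        log_hr = float(np.clip(log_hr, -10, 10))
    p = float(2 * stats.norm.sf(abs(log_hr / se))) if se > 0 else np.nan
    return log_hr, se, p


def logrank_test(times, events, group) -> float:
    """Two-group log-rank test P value (chi-square, 1 df)."""
    from lifelines.statistics import logrank_test as _lr

    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group, int)
    res = _lr(t[g == 0], t[g == 1], event_observed_A=e[g == 0], event_observed_B=e[g == 1])
    return float(res.p_value)


def ph_test(times, events, group, time_transform: str = "km") -> float:
    """Generalized Schoenfeld-residual test of proportional hazards.

    Correlates scaled Schoenfeld residuals with a transform of time
    (default: the KM-based transform, as in ``cox.zph``); returns the
    two-sided P value.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group, int)
    if e.sum() < 2:
        raise ValueError("proportional-hazards test needs at least 2 events")
    df = pd.DataFrame({"T": t, "E": e, "g": g})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    res = proportional_hazard_test(cph, df, time_transform=time_transform)
    return float(np.asarray(res.p_value).ravel()[0])
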