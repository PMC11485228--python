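"""Resampling inference and follow-up alignment.

* Sex-moderation permutation test: the observed statistic is the
  absolute difference between the female and male two-era RMTL ratios;
  each permutation re-allocates individuals to pseudo-sex groups of the
  original sizes (era membership preserved by default) and the P value
  is (1 + n_>) / (1 + n).
* Matched-pair bootstrap: pairs are resampled with replacement (both
  members together) and the RMTL ratio recomputed, giving a percentile
  CI and a two-sided resampling P value.
* Follow-up alignment: administrative censoring at the shorter of the
  two cohorts' horizons (cohort-wise) or of each matched pair's two
  follow-up ends (pairwise).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import km_fit, km_rmtl, rmtl as _rmtl


@dataclass(frozen=True)
class PermutationResult:
    observed_abs_diff: float
    n_perm: int
    n_exceed: int
    p_value: float
    ratio_f: float
    ratio_m: float
    n_degenerate: int = 0

    def __post_init__(self):
        expected = (1 + self.n_exceed) / (1 + self.n_perm)
        assert abs(self.p_value - expected) < 1e-12


@dataclass(frozen=True)
class BootstrapResult:
    n_boot: int
    estimates: np.ndarray
    ci: tuple[float, float]
    p_value: float
    point: float
    n_redrawn: int = 0


def permutation_p(n_exceed: int, n_perm: int) -> float:
    """P = (1 + n_>) / (1 + n): floors at 1/(1+n), never exactly zero."""
    if not 0 <= n_exceed <= n_perm:
        raise ValueError("need 0 <= n_exceed <= n_perm")
    return (1 + n_exceed) / (1 + n_perm)


def _ratio(times, events, is_primary, tau) -> float:
    """Primary/comparator RMTL ratio; nan when either RMTL is zero."""
    rp = km_rmtl(times[is_primary], events[is_primary], tau)
    rc = km_rmtl(times[~is_primary], events[~is_primary], tau)
    if rp.rmtl <= 0 or rc.rmtl <= 0:
        return np.nan
    return rp.rmtl / rc.rmtl


def permutation_moderation(
    df: pd.DataFrame,
    outcome: str,
    n_perm: int = 1000,
    seed: int = 0,
    tau: float = 5.75,
    era_preserving: bool = True,
) -> PermutationResult:
    """Permutation test for moderation of the era effect by sex.

    ``df`` needs columns era, sex (rows with sex 'F'/'M' are used) and
    ``<outcome>_time`` / ``<outcome>_event``.  A permutation in which
    any stratum's RMTL degenerates to zero is conservatively counted as
    exceeding the observed difference.
    """
    sub = df[df["sex"].isin(["F", "M"])]
    times = sub[f"{outcome}_time"].to_numpy(float)
    events = sub[f"{outcome}_event"].to_numpy(int)
    is_primary = (sub["era"] == "primary").to_numpy()
    is_f = (sub["sex"] == "F").to_numpy()
    for prim in (True, False):
        for female in (True, False):
            if not np.any((is_primary == prim) & (is_f == female)):
                raise ValueError("all four sex-by-era strata must be non-empty")

    def stat(female_mask):
        rf = _ratio(times[female_mask], events[female_mask], is_primary[female_mask], tau)
        rm = _ratio(times[~female_mask], events[~female_mask], is_primary[~female_mask], tau)
        return rf, rm

    obs_f, obs_m = stat(is_f)
    if np.isnan(obs_f) or np.isnan(obs_m):
        raise ValueError("degenerate (zero-RMTL) stratum in the observed data")
    observed = abs(obs_f - obs_m)

    rng = np.random.default_rng(seed)
    n_exceed = 0
    n_degenerate = 0
    idx_by_era = [np.flatnonzero(~is_primary), np.flatnonzero(is_primary)]
    for _ in range(n_perm):
        perm_f = np.zeros_like(is_f)
        if era_preserving:
            for idx in idx_by_era:
                k = int(is_f[idx].sum())
                perm_f[rng.choice(idx, size=k, replace=False)] = True
        else:
            k = int(is_f.sum())
            perm_f[rng.choice(len(is_f), size=k, replace=False)] = True
        rf, rm = stat(perm_f)
        if np.isnan(rf) or np.isnan(rm):
            n_degenerate += 1
            n_exceed += 1  # conservative
        elif abs(rf - rm) > observed:
            n_exceed += 1
    p = permutation_p(n_exceed, n_perm)
    return PermutationResult(
        observed_abs_diff=float(observed), n_perm=n_perm, n_exceed=n_exceed,
        p_value=p, ratio_f=float(obs_f), ratio_m=float(obs_m),
        n_degenerate=n_degenerate,
    )


def pair_bootstrap_rmtl(
    pair_data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    tau: float = 5.75,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Bootstrap of matched pairs for the RMTL ratio.

    ``pair_data`` has one row per pair with columns
    comparator_time, comparator_event, primary_time, primary_event.
    Resamples with zero events in either group are redrawn (counted).
    """
    tc = pair_data["comparator_time"].to_numpy(float)
    ec = pair_data["comparator_event"].to_numpy(int)
    tp = pair_data["primary_time"].to_numpy(float)
    ep = pair_data["primary_event"].to_numpy(int)
    n = len(pair_data)
    if n == 0:
        raise ValueError("no matched pairs")
    point_p = km_rmtl(tp, ep, tau)
    point_c = km_rmtl(tc, ec, tau)
    point = point_p.rmtl / point_c.rmtl
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(50):
            idx = rng.integers(0, n, n)
            if ec[idx].sum() > 0 and ep[idx].sum() > 0:
                break
            n_redrawn += 1
        cp = km_fit(tp[idx], ep[idx])
        cc = km_fit(tc[idx], ec[idx])
        # clamp the horizon only when a resample lacks support up to tau
        tau_b = tau
        for c in (cp, cc):
            if c.max_time() < tau and c.survival[-1] > 0:
                tau_b = min(tau_b, c.max_time())
        rp = _rmtl(cp, tau_b)
        rc = _rmtl(cc, tau_b)
        estimates[b] = rp.rmtl / rc.rmtl if rc.rmtl > 0 else np.nan
    est = estimates[np.isfinite(estimates)]
    lo, hi = np.quantile(est, [alpha / 2, 1 - alpha / 2])
    frac_le = np.mean(est <= 1.0)
    frac_ge = np.mean(est >= 1.0)
    p = max(min(2 * min(frac_le, frac_ge), 1.0), 1.0 / n_boot)
    return BootstrapResult(
        n_boot=n_boot, estimates=estimates, ci=(float(lo), float(hi)),
        p_value=float(p), point=float(point), n_redrawn=n_redrawn,
    )


def _apply_cut(df: pd.DataFrame, cut: np.ndarray) -> pd.DataFrame:
    """Administratively censor every outcome (and follow-up end) at cut."""
    out = df.copy()
    outcomes = [c[: -len("_time")] for c in df.columns if c.endswith("_time")]
    for name in outcomes:
        t = out[f"{name}_time"].to_numpy(float)
        e = out[f"{name}_event"].to_numpy(int)
        over = t > cut
        out[f"{name}_time"] = np.where(over, cut, t)
        out[f"{name}_event"] = np.where(over, 0, e)
    out["followup_end_years"] = np.minimum(out["followup_end_years"].to_numpy(float), cut)
    return out


def align_followup(
    df: pd.DataFrame,
    mode: str = "cohortwise",
    pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Align administrative follow-up horizons between cohorts.

    cohortwise: both cohorts censored at the minimum of the two cohorts'
    maximum follow-up.  pairwise: each matched pair censored at the
    minimum of its two follow-up ends (requires ``pairs`` with
    comparator_id/primary_id; returns matched rows only).
    Never lengthens follow-up; event counts can only decrease.
    """
    if mode == "cohortwise":
        cut = min(
            df.loc[df["era"] == era, "followup_end_years"].max()
            for era in ("comparator", "primary")
        )
        return _apply_cut(df, np.full(len(df), cut))
    if mode == "pairwise":
        if pairs is None or not {"comparator_id", "primary_id"} <= set(pairs.columns):
            raise ValueError("pairwise alignment requires a pairs table with ids")
        by_id = df.set_index("patient_id")
        fup = by_id["followup_end_years"]
        pair_cut = np.minimum(
            fup.loc[pairs["comparator_id"]].to_numpy(),
            fup.loc[pairs["primary_id"]].to_numpy(),
        )
        rows = pd.concat(
            [by_id.loc[pairs["comparator_id"]], by_id.loc[pairs["primary_id"]]]
        ).reset_index()
        cuts = np.concatenate([pair_cut, pair_cut])
        return _apply_cut(rows, cuts)
    raise ValueError("mode must be 'cohortwise' or 'pairwise'")
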