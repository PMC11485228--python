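"""Config-driven orchestration of the two-era analysis grid.

Each :class:`AnalysisConfig` describes one row of a results table:
match (propensity or coarsened-exact) → align follow-up → landmark →
Kaplan–Meier → proportional-hazards diagnostic → RMTL comparison
(parametric or matched-pair bootstrap variance) → optionally a Cox /
log-rank analysis on a restricted follow-up and a sex-moderation
permutation test.  Matching never sees outcome columns.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, matching, survival
from .config import ConfigError

CORE_COLUMNS = {"patient_id", "era", "months_from_step", "followup_end_years"}


@dataclass(frozen=True)
class AnalysisConfig:
    outcome: str
    analysis_id: str = ""
    matching: str = "propensity"            # propensity | cem
    caliper: float = 0.1
    caliper_scale: str = "raw"              # raw | sd_logit
    covariates: tuple[str, ...] | None = None
    exposure_window_months: int | None = None
    landmark: float = 0.25
    horizon: float = 6.0
    followup_alignment: str = "none"        # none | cohortwise | pairwise
    restrict_followup: float | None = None  # years; triggers Cox/log-rank
    sex_stratify: bool = False
    variance: str = "parametric"            # parametric | bootstrap
    n_perm: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.horizon <= self.landmark:
            raise ConfigError("horizon must exceed the landmark time")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.matching not in ("propensity", "cem"):
            raise ConfigError("matching must be 'propensity' or 'cem'")
        if self.variance not in ("parametric", "bootstrap"):
            raise ConfigError("variance must be 'parametric' or 'bootstrap'")
        if self.followup_alignment not in ("none", "cohortwise", "pairwise"):
            raise ConfigError("unknown followup_alignment")
        if self.followup_alignment == "pairwise" and self.matching != "cem":
            # pairwise alignment and the pair bootstrap need stratified pairs
            pass

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def label(self) -> str:
        return self.analysis_id or f"{self.outcome}/{self.matching}"


def default_covariates(df: pd.DataFrame) -> tuple[str, ...]:
    """All baseline columns: demographics plus every covariate column,
    never outcome or follow-up columns."""
    out = []
    for c in df.columns:
        if c in CORE_COLUMNS or c.endswith(("_time", "_event")):
            continue
        out.append(c)
    return tuple(out)


def _landmark_subset(df: pd.DataFrame, outcome: str, landmark: float):
    """Drop subjects whose outcome time is at/before the landmark and
    re-origin time at the landmark."""
    t = df[f"{outcome}_time"].to_numpy(float)
    keep = t > landmark
    sub = df.loc[keep].copy()
    sub[f"{outcome}_time"] = sub[f"{outcome}_time"] - landmark
    return sub


def _restrict(df: pd.DataFrame, outcome: str, cut: float) -> pd.DataFrame:
    t = df[f"{outcome}_time"].to_numpy(float)
    e = df[f"{outcome}_event"].to_numpy(int)
    over = t > cut
    out = df.copy()
    out[f"{outcome}_time"] = np.where(over, cut, t)
    out[f"{outcome}_event"] = np.where(over, 0, e)
    return out


def _compare(sub: pd.DataFrame, outcome: str, tau: float, alpha: float):
    """KM + RMTL comparison on a landmarked analysis set."""
    g = (sub["era"] == "primary").to_numpy()
    t = sub[f"{outcome}_time"].to_numpy(float)
    e = sub[f"{outcome}_event"].to_numpy(int)
    tau_eff = min(tau, float(t[g].max()), float(t[~g].max()))
    curve_c = survival.km_fit(t[~g], e[~g])
    curve_p = survival.km_fit(t[g], e[g])
    cmp_ = survival.rmtl_compare(
        survival.rmtl(curve_p, tau_eff), survival.rmtl(curve_c, tau_eff), alpha
    )
    return cmp_, tau_eff, (curve_c, curve_p), (t, e, g)


def run_analysis(
    cohort: pd.DataFrame, config: AnalysisConfig, outdir: str | Path | None = None
) -> dict:
    """Execute one analysis; returns a results row (dict).

    On zero matched pairs returns a structured failure row rather than
    raising.
    """
    df = cohort
    if f"{config.outcome}_time" not in df.columns:
        raise ConfigError(f"outcome {config.outcome!r} not in cohort table")
    covs = tuple(config.covariates) if config.covariates else default_covariates(df)

    if config.exposure_window_months is not None:
        df = df[np.abs(df["months_from_step"]) <= config.exposure_window_months]

    # matching (covariates only; outcome columns are firewalled)
    if config.matching == "propensity":
        model = matching.fit_propensity(df, covs)
        era = pd.Series(df["era"].to_numpy(), index=df["patient_id"].to_numpy())
        matched = matching.match_nearest(
            era, model.scores, config.caliper, config.seed, config.caliper_scale
        )
        balance_covs = covs
    else:
        spec = matching.CoarseningSpec(variables=covs)
        matched = matching.coarsened_exact_match(df, spec, config.seed)
        balance_covs = covs
    matched.balance_table = matching.balance_table(df, balance_covs, matched)

    row = {
        "analysis_id": config.label,
        "outcome": config.outcome,
        "matching": config.matching,
        "n_comparator": matched.n_pairs,
        "n_primary": matched.n_pairs,
        "seed": config.seed,
        "config_hash": config.hash(),
        "status": "ok",
    }
    if matched.n_pairs == 0:
        row["status"] = "failed: zero matched pairs"
        return row

    ids = matched.matched_ids()
    if config.followup_alignment == "pairwise":
        adf = inference.align_followup(df, "pairwise", matched.pairs)
    elif config.followup_alignment == "cohortwise":
        adf = inference.align_followup(df[df["patient_id"].isin(ids)], "cohortwise")
    else:
        adf = df[df["patient_id"].isin(ids)]

    tau = config.horizon - config.landmark
    if config.restrict_followup is not None:
        adf = _restrict(adf, config.outcome, config.restrict_followup)
        tau = min(tau, config.restrict_followup - config.landmark)

    sub = _landmark_subset(adf, config.outcome, config.landmark)
    cmp_, tau_eff, curves, (t, e, g) = _compare(sub, config.outcome, tau, config.alpha)

    row.update(
        tau=tau_eff,
        rmtl_comparator=cmp_.rmtl_comparator.rmtl,
        rmtl_primary=cmp_.rmtl_primary.rmtl,
        rmtl_ratio=cmp_.ratio,
        ci_low=cmp_.ci[0], ci_high=cmp_.ci[1], p_value=cmp_.p_value,
        additional_days=cmp_.additional_days,
        ad_ci_low=cmp_.additional_days_ci[0],
        ad_ci_high=cmp_.additional_days_ci[1],
    )
    try:
        row["ph_p"] = survival.ph_test(t, e, g.astype(int))
    except ValueError:
        row["ph_p"] = np.nan

    if config.variance == "bootstrap":
        pair_data = _pair_outcome_table(adf, matched.pairs, config.outcome, config.landmark)
        boot = inference.pair_bootstrap_rmtl(
            pair_data, config.n_boot, config.seed, tau_eff, config.alpha
        )
        row.update(
            rmtl_ratio=boot.point, ci_low=boot.ci[0], ci_high=boot.ci[1],
            p_value=boot.p_value, variance="bootstrap",
        )

    if config.restrict_followup is not None:
        log_hr, se, wald_p = survival.cox_fit(t, e, g.astype(int))
        zq = 1.959963984540054
        row.update(
            cox_hr=float(np.exp(log_hr)),
            cox_ci_low=float(np.exp(log_hr - zq * se)),
            cox_ci_high=float(np.exp(log_hr + zq * se)),
            logrank_p=survival.logrank_test(t, e, g.astype(int)),
        )

    if config.sex_stratify:
        for sex, key in (("F", "f"), ("M", "m")):
            ssub = sub[sub["sex"] == sex]
            try:
                scmp, stau, _, _ = _compare(ssub, config.outcome, tau, config.alpha)
                row[f"rmtl_ratio_{key}"] = scmp.ratio
                row[f"ci_low_{key}"] = scmp.ci[0]
                row[f"ci_high_{key}"] = scmp.ci[1]
            except (ValueError, survival.HorizonError):
                row[f"rmtl_ratio_{key}"] = np.nan
        if config.n_perm > 0:
            perm = inference.permutation_moderation(
                sub, config.outcome, config.n_perm, config.seed, tau_eff
            )
            row["moderation_p"] = perm.p_value
            row["moderation_observed"] = perm.observed_abs_diff

    if outdir is not None:
        _write_artifacts(Path(outdir), config, row, matched, curves)
    return row


def _pair_outcome_table(
    df: pd.DataFrame, pairs: pd.DataFrame, outcome: str, landmark: float
) -> pd.DataFrame:
    """Per-pair outcome times (pairs with either member failing the
    landmark are dropped, keeping the pairing intact)."""
    by_id = df.set_index("patient_id")
    tc = by_id.loc[pairs["comparator_id"], f"{outcome}_time"].to_numpy(float)
    ec = by_id.loc[pairs["comparator_id"], f"{outcome}_event"].to_numpy(int)
    tp = by_id.loc[pairs["primary_id"], f"{outcome}_time"].to_numpy(float)
    ep = by_id.loc[pairs["primary_id"], f"{outcome}_event"].to_numpy(int)
    keep = (tc > landmark) & (tp > landmark)
    return pd.DataFrame(
        {
            "comparator_time": tc[keep] - landmark,
            "comparator_event": ec[keep],
            "primary_time": tp[keep] - landmark,
            "primary_event": ep[keep],
        }
    )


def _curve_frame(curve: survival.SurvivalCurve) -> pd.DataFrame:
    se = np.sqrt(curve.greenwood_var)
    z = 1.959963984540054
    return pd.DataFrame(
        {
            "time": curve.times,
            "survival": curve.survival,
            "ci_low": np.clip(curve.survival - z * se, 0, 1),
            "ci_high": np.clip(curve.survival + z * se, 0, 1),
            "n_risk": curve.n_risk,
        }
    )


def _write_artifacts(outdir: Path, config, row, matched, curves) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    stem = config.label.replace("/", "_")
    curve_c, curve_p = curves
    _curve_frame(curve_c).to_csv(outdir / f"{stem}_km_comparator.csv", index=False)
    _curve_frame(curve_p).to_csv(outdir / f"{stem}_km_primary.csv", index=False)
    matched.balance_table.to_csv(outdir / f"{stem}_balance.csv", index=False)
    matched.pairs.to_csv(outdir / f"{stem}_pairs.csv", index=False)
    with open(outdir / f"{stem}_provenance.json", "w") as fh:
        json.dump(
            {"config": asdict(config), "config_hash": config.hash(), "row": _plain(row)},
            fh, indent=2, sort_keys=True,
        )


def _plain(row: dict) -> dict:
    return {
        k: (v.item() if hasattr(v, "item") else v)
        for k, v in row.items()
    }


def run_grid(
    cohort: pd.DataFrame, configs, outdir: str | Path | None = None
) -> pd.DataFrame:
    """One results row per analysis config; per-row failures isolated."""
    rows = []
    for cfg in configs:
        try:
            rows.append(run_analysis(cohort, cfg, outdir))
        except Exception as exc:  # per-row isolation
            rows.append(
                {
                    "analysis_id": cfg.label, "outcome": cfg.outcome,
                    "matching": cfg.matching, "seed": cfg.seed,
                    "config_hash": cfg.hash(), "status": f"failed: {exc}",
                }
            )
    table = pd.DataFrame(rows)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(outdir) / "results.csv", index=False)
    return table


def default_grid(outcomes=("dementia", "zoster", "mortality", "negative_control"),
                 seed: int = 0) -> list[AnalysisConfig]:
    """The study's analysis grid on a synthetic cohort: primary analysis
    per outcome, plus aligned-horizon, restricted-window, sex-stratified,
    pre-pandemic-restricted and CEM variants of the dementia analysis."""
    grid = [
        AnalysisConfig(outcome=o, analysis_id=f"primary_{o}", seed=seed)
        for o in outcomes
    ]
    grid += [
        AnalysisConfig(outcome="dementia", analysis_id="aligned_cohortwise",
                       followup_alignment="cohortwise", seed=seed),
        AnalysisConfig(outcome="dementia", analysis_id="window_6m",
                       exposure_window_months=6, seed=seed),
        AnalysisConfig(outcome="dementia", analysis_id="sex_stratified",
                       sex_stratify=True, seed=seed),
        AnalysisConfig(outcome="dementia", analysis_id="precovid_18m",
                       restrict_followup=1.5, seed=seed),
        AnalysisConfig(outcome="dementia", analysis_id="cem_parametric",
                       matching="cem",
                       covariates=("age_years", "sex", "race", "comorb_00",
                                   "comorb_05", "comorb_10"),
                       seed=seed),
        AnalysisConfig(outcome="dementia", analysis_id="cem_bootstrap",
                       matching="cem", variance="bootstrap",
                       covariates=("age_years", "sex", "race", "comorb_00",
                                   "comorb_05", "comorb_10"),
                       seed=seed),
        AnalysisConfig(outcome="dementia", analysis_id="cem_aligned_pairwise",
                       matching="cem", followup_alignment="pairwise",
                       covariates=("age_years", "sex", "race", "comorb_00",
                                   "comorb_05", "comorb_10"),
                       seed=seed),
    ]
    return grid
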