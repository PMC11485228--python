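"""Seeded synthetic two-era cohort generation.

Event times are drawn by inverting the piecewise-constant cumulative
hazard implied by each outcome's baseline rates, covariate effects, the
(possibly time-varying) era effect and the sex interaction.  Death acts
as a competing risk implemented as censoring for the other outcomes:
``followup_end_years`` is min(administrative cap, dropout, death).

Each source of randomness has its own named generator stream so that,
e.g., adding a covariate to a scenario does not perturb event draws.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ERAS, ConfigError, OutcomeSpec, SimulationConfig

TIME_DECIMALS = 6
SEX_LEVELS = ("F", "M", "missing")
MISSING = "missing"


@dataclass(frozen=True)
class PatientRecord:
    """A single-subject view of one cohort-table row."""

    patient_id: str
    era: str
    age_years: int
    sex: str
    covariates: Mapping[str, object]
    outcome_events: Mapping[str, tuple[float, int]]
    followup_end_years: float
    months_from_step: int = 0


def _stream(seed: int, concern: str) -> np.random.Generator:
    """Named RNG stream: stable under reordering of other concerns."""
    return np.random.default_rng([seed, zlib.crc32(concern.encode())])


def _draw_event_times(
    spec: OutcomeSpec, lp: np.ndarray, is_primary: np.ndarray,
    is_female: np.ndarray, horizon: float, rng: np.random.Generator,
) -> np.ndarray:
    """Invert the piecewise-constant cumulative hazard; inf = no event."""
    breaks = np.unique(
        np.concatenate([spec.baseline_hazard.breaks, spec.era_log_hr.breaks, [horizon]])
    )
    breaks = breaks[breaks <= horizon + 1e-12]
    left = np.concatenate([[0.0], breaks[:-1]])
    widths = breaks - left
    mid = 0.5 * (left + breaks)
    base = spec.baseline_hazard.at(mid)  # (k,)
    era_term = spec.era_log_hr.at(mid)  # (k,)
    n = lp.shape[0]
    era_lp = np.where(is_primary, 1.0, 0.0)[:, None] * (
        era_term[None, :]
        + np.where(is_female, spec.sex_interaction_log_hr, 0.0)[:, None]
    )
    rates = base[None, :] * np.exp(lp[:, None] + era_lp)  # (n, k)
    cumh = np.cumsum(rates * widths[None, :], axis=1)
    e = rng.exponential(size=n)
    piece = np.argmax(cumh >= e[:, None], axis=1)
    no_event = cumh[:, -1] < e
    prev_cum = np.where(piece > 0, np.take_along_axis(cumh, np.maximum(piece - 1, 0)[:, None], 1)[:, 0], 0.0)
    rate_at = np.take_along_axis(rates, piece[:, None], 1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = left[piece] + (e - prev_cum) / rate_at
    t = np.where(no_event | ~np.isfinite(t), np.inf, t)
    return t


def generate_cohorts(config: SimulationConfig) -> pd.DataFrame:
    """Generate a synthetic two-era cohort table.

    Returns one row per patient with columns
    ``patient_id, era, months_from_step, age_years, sex, <covariates...>,
    <outcome>_time, <outcome>_event, followup_end_years``.
    Deterministic: identical config (including seed) gives an identical
    table.
    """
    seed = config.seed
    n = {era: m for era, m in zip(ERAS, (config.n_comparator, config.n_primary))}
    total = config.n_comparator + config.n_primary
    era = np.repeat(ERAS, [n["comparator"], n["primary"]])
    is_primary = era == "primary"

    # demographics -----------------------------------------------------
    rng_sex = _stream(seed, "sex")
    p_female = np.where(is_primary, config.sex_prob["primary"], config.sex_prob["comparator"])
    true_female = rng_sex.random(total) < p_female
    rng_age = _stream(seed, "age")
    age = np.empty(total)
    for e in ERAS:
        mean, sd = config.age_mean_sd[e]
        m = era == e
        age[m] = rng_age.normal(mean, sd, m.sum())
    age = np.clip(np.rint(age), 65, 99).astype(int)

    cols: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i:07d}" for i in range(total)]),
        "era": era,
        "age_years": age,
    }
    rng_entry = _stream(seed, "entry")
    span = config.censoring.entry_span_months
    months = np.empty(total, dtype=int)
    for e in ERAS:
        m = era == e
        if config.censoring.entry_profile[e] == "ramp":
            w = np.arange(1, span + 1, dtype=float)
            w /= w.sum()
            months[m] = rng_entry.choice(np.arange(1, span + 1), m.sum(), p=w)
        else:
            months[m] = rng_entry.integers(1, span + 1, m.sum())
    months = np.where(is_primary, months, -months)
    cols["months_from_step"] = months

    # covariates -------------------------------------------------------
    cov_values: dict[str, np.ndarray] = {}
    for spec in config.covariates:
        rng_c = _stream(seed, f"covariate:{spec.name}")
        if spec.kind == "binary":
            p = np.where(
                is_primary, float(spec.by_era["primary"]), float(spec.by_era["comparator"])
            )
            cov_values[spec.name] = (rng_c.random(total) < p).astype(int)
        elif spec.kind == "categorical":
            u = rng_c.random(total)
            out = np.empty(total, dtype=object)
            for e in ERAS:
                m = era == e
                cum = np.cumsum(spec.by_era[e])
                out[m] = np.asarray(spec.levels, dtype=object)[
                    np.searchsorted(cum, u[m], side="right").clip(0, len(spec.levels) - 1)
                ]
            cov_values[spec.name] = out
        else:  # age-kind covariates are redundant with age_years; re-draw
            out = np.empty(total)
            for e in ERAS:
                mean, sd = spec.by_era[e]
                m = era == e
                out[m] = rng_c.normal(mean, sd, m.sum())
            cov_values[spec.name] = np.clip(np.rint(out), 65, 99).astype(int)

    # linear predictors and event draws --------------------------------
    horizon = config.censoring.max_followup
    event_time: dict[str, np.ndarray] = {}
    for spec in config.outcomes:
        lp = np.zeros(total)
        for key, beta in spec.log_hr_covariates.items():
            if key == "age":
                lp += beta * (age - 75.0)
            elif key == "sex_F":
                lp += beta * true_female
            elif "=" in key:
                name, level = key.split("=", 1)
                lp += beta * (cov_values[name] == level)
            else:
                lp += beta * cov_values[key]
        rng_o = _stream(seed, f"events:{spec.name}")
        event_time[spec.name] = _draw_event_times(
            spec, lp, is_primary, true_female, horizon, rng_o
        )

    # censoring --------------------------------------------------------
    cap = config.censoring.cap_for(months)
    rng_drop = _stream(seed, "dropout")
    if config.censoring.dropout_rate > 0:
        drop = rng_drop.exponential(1.0 / config.censoring.dropout_rate, total)
    else:
        drop = np.full(total, np.inf)
    followup = np.minimum(cap, drop)
    for spec in config.outcomes:
        if spec.is_mortality:
            followup = np.minimum(followup, event_time[spec.name])
    followup = np.round(followup, TIME_DECIMALS)

    for spec in config.outcomes:
        t = event_time[spec.name]
        observed = t <= followup
        cols[f"{spec.name}_time"] = np.round(np.where(observed, t, followup), TIME_DECIMALS)
        cols[f"{spec.name}_event"] = observed.astype(int)
    cols["followup_end_years"] = followup

    # recorded sex, with missingness applied last ----------------------
    rng_miss = _stream(seed, "missing")
    sex = np.where(true_female, "F", "M").astype(object)
    if config.missing_rate > 0:
        sex[rng_miss.random(total) < config.missing_rate] = MISSING
    cols["sex"] = sex
    if config.missing_rate > 0:
        for spec in config.covariates:
            if spec.missingable and spec.kind == "categorical":
                v = cov_values[spec.name].copy()
                v[rng_miss.random(total) < config.missing_rate] = MISSING
                cov_values[spec.name] = v

    order = ["patient_id", "era", "months_from_step", "age_years", "sex"]
    df = pd.DataFrame(cols)
    for spec in config.covariates:
        df[spec.name] = cov_values[spec.name]
        order.append(spec.name)
    order += [f"{o}_{s}" for o in config.outcome_names for s in ("time", "event")]
    order.append("followup_end_years")
    return df[order].copy()


# -- cohort-table I/O --------------------------------------------------

def _outcome_names(columns) -> list[str]:
    return [c[: -len("_time")] for c in columns if c.endswith("_time")]


def validate_cohort(df: pd.DataFrame) -> None:
    """Enforce per-record invariants; raises ConfigError naming the row."""
    required = {"patient_id", "era", "age_years", "sex", "followup_end_years"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"cohort table missing columns: {sorted(missing)}")
    bad_era = ~df["era"].isin(ERAS)
    if bad_era.any():
        raise ConfigError(f"unknown era label at row {int(np.argmax(bad_era.to_numpy()))}")
    if (df["age_years"] < 65).any():
        raise ConfigError(
            f"age below eligibility floor at row {int((df['age_years'] < 65).idxmax())}"
        )
    fup = df["followup_end_years"].to_numpy(float)
    if (fup <= 0).any() or not np.isfinite(fup).all():
        raise ConfigError("non-positive or non-finite follow-up time")
    for name in _outcome_names(df.columns):
        t = df[f"{name}_time"].to_numpy(float)
        e = df[f"{name}_event"].to_numpy(int)
        if (t < 0).any():
            raise ConfigError(f"negative {name} time at row {int(np.argmax(t < 0))}")
        if (t > fup + 1e-9).any():
            raise ConfigError(f"{name} time exceeds follow-up end")
        bad = (e == 0) & (np.abs(t - fup) > 1e-9)
        if bad.any():
            raise ConfigError(
                f"censored {name} time differs from follow-up end at row "
                f"{int(np.argmax(bad))}"
            )


def write_cohort_table(df: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 CSV (times already in years)."""
    validate_cohort(df)
    df.to_csv(path, index=False, float_format=f"%.{TIME_DECIMALS}f")


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort table written by :func:`write_cohort_table`."""
    df = pd.read_csv(path, dtype={"patient_id": str, "era": str, "sex": str})
    for name in _outcome_names(df.columns):
        df[f"{name}_time"] = df[f"{name}_time"].astype(float)
        df[f"{name}_event"] = df[f"{name}_event"].astype(int)
    validate_cohort(df)
    return df


def to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Materialise :class:`PatientRecord` views (convenience accessor)."""
    outcomes = _outcome_names(df.columns)
    core = {
        "patient_id", "era", "months_from_step", "age_years", "sex",
        "followup_end_years",
    } | {f"{o}_{s}" for o in outcomes for s in ("time", "event")}
    cov_cols = [c for c in df.columns if c not in core]
    records = []
    for row in df.itertuples(index=False):
        r = row._asdict()
        records.append(
            PatientRecord(
                patient_id=r["patient_id"],
                era=r["era"],
                age_years=int(r["age_years"]),
                sex=r["sex"],
                covariates={c: r[c] for c in cov_cols},
                outcome_events={
                    o: (float(r[f"{o}_time"]), int(r[f"{o}_event"])) for o in outcomes
                },
                followup_end_years=float(r["followup_end_years"]),
                months_from_step=int(r.get("months_from_step", 0)),
            )
        )
    return records
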