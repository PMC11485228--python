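"""Configuration objects for the synthetic two-era cohort generator.

The generator emulates an EHR extract around a step-change natural
experiment: two vaccination eras ("comparator" before the step,
"primary" after), ~60 baseline covariates whose prevalence may drift
between eras, and per-outcome event times drawn from piecewise-constant
hazards with an era effect that may vary (wane) over follow-up.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

ERAS = ("comparator", "primary")


class ConfigError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


def _check_prob(p: float, what: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{what} must be in [0, 1], got {p!r}")


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate with era-specific distribution.

    kind "binary": ``by_era[era]`` is a single prevalence.
    kind "categorical": ``levels`` plus per-era level probabilities.
    kind "age": ``by_era[era]`` is (mean, sd) of a normal truncated and
    rounded to integer years, floored at the eligibility age of 65.
    """

    name: str
    kind: str  # binary | categorical | age
    by_era: Mapping[str, Sequence[float] | float]
    levels: tuple[str, ...] = ()
    missingable: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "age"):
            raise ConfigError(f"unknown covariate kind {self.kind!r}")
        for era in ERAS:
            if era not in self.by_era:
                raise ConfigError(f"covariate {self.name!r} missing era {era!r}")
        if self.kind == "binary":
            for era in ERAS:
                _check_prob(float(self.by_era[era]), f"{self.name} prevalence ({era})")
        elif self.kind == "categorical":
            if not self.levels:
                raise ConfigError(f"categorical covariate {self.name!r} needs levels")
            for era in ERAS:
                probs = list(self.by_era[era])
                if len(probs) != len(self.levels):
                    raise ConfigError(
                        f"{self.name}: {len(probs)} probabilities for "
                        f"{len(self.levels)} levels ({era})"
                    )
                for p in probs:
                    _check_prob(p, f"{self.name} level probability ({era})")
                if abs(sum(probs) - 1.0) > 1e-8:
                    raise ConfigError(f"{self.name}: level probabilities must sum to 1 ({era})")
        else:  # age
            for era in ERAS:
                mean, sd = self.by_era[era]
                if mean < 65 or sd <= 0:
                    raise ConfigError(f"{self.name}: age mean must be >= 65 and sd > 0")


@dataclass(frozen=True)
class PiecewiseConstant:
    """A piecewise-constant function of follow-up time.

    ``breaks`` are the right edges of consecutive bins starting at 0;
    the last break is the simulation horizon.  ``values[i]`` applies on
    [breaks[i-1], breaks[i]).  Beyond the last break the final value is
    carried forward.
    """

    breaks: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.breaks) != len(self.values):
            raise ConfigError("breaks and values must have equal length")
        if not self.breaks:
            raise ConfigError("piecewise function needs at least one bin")
        prev = 0.0
        for b in self.breaks:
            if b <= prev:
                raise ConfigError("breaks must be strictly increasing and positive")
            prev = b

    @classmethod
    def constant(cls, value: float, horizon: float = 6.0) -> "PiecewiseConstant":
        return cls((horizon,), (value,))

    def at(self, t):
        """Evaluate at time(s) t (vectorised)."""
        import numpy as np

        idx = np.searchsorted(np.asarray(self.breaks), np.asarray(t), side="right")
        idx = np.minimum(idx, len(self.values) - 1)
        return np.asarray(self.values)[idx]


@dataclass(frozen=True)
class OutcomeSpec:
    """Data-generating law for one time-to-event outcome.

    The hazard for a subject is
    ``baseline(t) * exp(sum covariate effects + era(t) + sex interaction)``
    where the era term applies only in the primary era and the sex
    interaction only to primary-era females.  A negative-control outcome
    has ``era_log_hr`` identically zero and no sex interaction.
    """

    name: str
    baseline_hazard: PiecewiseConstant
    log_hr_covariates: Mapping[str, float] = field(default_factory=dict)
    era_log_hr: PiecewiseConstant = field(
        default_factory=lambda: PiecewiseConstant.constant(0.0)
    )
    sex_interaction_log_hr: float = 0.0
    is_mortality: bool = False

    def __post_init__(self) -> None:
        for r in self.baseline_hazard.values:
            if r < 0:
                raise ConfigError(f"outcome {self.name!r}: negative baseline rate")


@dataclass(frozen=True)
class CensoringSpec:
    """Era-dependent administrative censoring plus random dropout.

    Subjects enter uniformly over ``entry_span_months`` within their
    era's window (month 0 is the step change; the step month itself is
    excluded, so entry months are 1..span on either side).  Follow-up is
    administratively capped at
    ``min(max_followup, data_cutoff - entry_calendar_years)`` and ends
    earlier on exponential dropout at ``dropout_rate`` per year.
    """

    entry_span_months: int = 36
    max_followup: float = 6.0
    data_cutoff: float = 6.5  # calendar years after the step change
    dropout_rate: float = 0.04
    # entry-month profile per era: "uniform", or "ramp" (linearly
    # increasing uptake, emulating the recombinant vaccine's adoption)
    entry_profile: Mapping[str, str] = field(
        default_factory=lambda: {"comparator": "uniform", "primary": "ramp"}
    )

    def __post_init__(self) -> None:
        if self.entry_span_months <= 0 or self.max_followup <= 0 or self.dropout_rate < 0:
            raise ConfigError("invalid censoring specification")
        if self.data_cutoff - self.entry_span_months / 12.0 <= 0:
            raise ConfigError("data cutoff precedes the end of the primary entry window")
        for era in ERAS:
            if self.entry_profile[era] not in ("uniform", "ramp"):
                raise ConfigError("entry_profile must be 'uniform' or 'ramp'")

    def cap_for(self, months_from_step):
        """Administrative follow-up cap given signed entry month."""
        import numpy as np

        cal = np.asarray(months_from_step, dtype=float) / 12.0
        return np.minimum(self.max_followup, self.data_cutoff - cal)


@dataclass(frozen=True)
class SimulationConfig:
    n_comparator: int
    n_primary: int
    covariates: tuple[CovariateSpec, ...]
    outcomes: tuple[OutcomeSpec, ...]
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    sex_prob: Mapping[str, float] = field(
        default_factory=lambda: {"comparator": 0.55, "primary": 0.55}
    )
    age_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"comparator": (73.5, 6.0), "primary": (73.5, 6.0)}
    )
    missing_rate: float = 0.0
    landmark: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_comparator <= 0 or self.n_primary <= 0:
            raise ConfigError("cohort sizes must be positive")
        for era in ERAS:
            _check_prob(float(self.sex_prob[era]), f"sex probability ({era})")
        _check_prob(self.missing_rate, "missing_rate")
        names = [c.name for c in self.covariates] + [o.name for o in self.outcomes]
        if len(set(names)) != len(names):
            raise ConfigError("covariate/outcome names must be unique")
        min_cap = min(
            self.censoring.max_followup,
            self.censoring.data_cutoff - self.censoring.entry_span_months / 12.0,
        )
        if min_cap <= self.landmark:
            raise ConfigError("follow-up caps must exceed the landmark time")

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.outcomes)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = [asdict(c) for c in self.covariates]
        d["outcomes"] = [asdict(o) for o in self.outcomes]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["covariates"] = tuple(
            CovariateSpec(
                name=c["name"],
                kind=c["kind"],
                by_era={e: _tupleize(v) for e, v in c["by_era"].items()},
                levels=tuple(c.get("levels", ())),
                missingable=bool(c.get("missingable", False)),
            )
            for c in d["covariates"]
        )
        d["outcomes"] = tuple(
            OutcomeSpec(
                name=o["name"],
                baseline_hazard=_pw(o["baseline_hazard"]),
                log_hr_covariates=dict(o.get("log_hr_covariates", {})),
                era_log_hr=_pw(o.get("era_log_hr", {"breaks": [6.0], "values": [0.0]})),
                sex_interaction_log_hr=float(o.get("sex_interaction_log_hr", 0.0)),
                is_mortality=bool(o.get("is_mortality", False)),
            )
            for o in d["outcomes"]
        )
        cen = d.get("censoring", {})
        if isinstance(cen, Mapping):
            d["censoring"] = CensoringSpec(**cen)
        d["age_mean_sd"] = {e: tuple(v) for e, v in d["age_mean_sd"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _pw(d: Mapping) -> PiecewiseConstant:
    return PiecewiseConstant(tuple(d["breaks"]), tuple(d["values"]))


def _tupleize(v):
    return tuple(v) if isinstance(v, (list, tuple)) else float(v)


def _plain(obj):
    """Recursively convert to YAML-safe builtins."""
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj
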