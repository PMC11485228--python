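"""Generator: event-law oracles, calibration, invariants and round-trip I/O."""
import numpy as np
import pandas as pd
import pytest

from natexp import (
    CensoringSpec,
    ConfigError,
    CovariateSpec,
    OutcomeSpec,
    PiecewiseConstant,
    SimulationConfig,
    generate_cohorts,
    read_cohort_table,
    to_records,
    validate_cohort,
    write_cohort_table,
)
from natexp.scenarios import null_scenario, paper_like
from natexp.survival import logrank_test


def simple_config(rate=0.2, n=1000, seed=5, dropout=0.0, **kw):
    return SimulationConfig(
        n_comparator=n,
        n_primary=n,
        covariates=(),
        outcomes=(
            OutcomeSpec("evt", baseline_hazard=PiecewiseConstant.constant(rate)),
        ),
        censoring=CensoringSpec(entry_span_months=1, data_cutoff=8.0, dropout_rate=dropout),
        seed=seed,
        **kw,
    )


def test_zero_hazard_forces_censoring():
    df = generate_cohorts(simple_config(rate=0.0, n=300))
    assert (df["evt_event"] == 0).all()
    assert np.allclose(df["evt_time"], df["followup_end_years"])


def test_exponential_event_proportion_matches_closed_form():
    # constant hazard 0.2/yr, administrative cap ~6 y, no dropout:
    # P(event by 6) = 1 - exp(-1.2)
    n = 5000
    df = generate_cohorts(simple_config(rate=0.2, n=n // 2, seed=2))
    truth = 1 - np.exp(-1.2)
    se = np.sqrt(truth * (1 - truth) / (2 * (n // 2)))
    assert abs(df["evt_event"].mean() - truth) < 3 * se


def test_null_scenario_eras_share_one_law():
    # with no era effect and no drift, log-rank P should not reject
    # systematically across replicate seeds
    ps = []
    for seed in range(10):
        df = generate_cohorts(null_scenario(700, 700, seed=seed, n_comorbidities=4))
        g = (df["era"] == "primary").to_numpy(int)
        dfa = df[df["followup_end_years"] > 0]
        ps.append(
            logrank_test(
                df["dementia_time"].to_numpy(), df["dementia_event"].to_numpy(), g
            )
        )
    ps = np.asarray(ps)
    assert (ps < 0.05).sum() <= 3
    assert ps.max() > 0.2  # not degenerately small


def test_covariate_prevalence_calibrated_per_era(paper_like_cohort):
    df = paper_like_cohort
    cfg = paper_like(3000, 3600, seed=11)
    z = []
    for spec in cfg.covariates:
        if spec.kind != "binary":
            continue
        for era, n_era in (("comparator", 3000), ("primary", 3600)):
            p = float(spec.by_era[era])
            obs = df.loc[df["era"] == era, spec.name].mean()
            z.append((obs - p) / np.sqrt(p * (1 - p) / n_era))
    z = np.abs(z)
    # joint check over >100 margins: almost all within 3 SE, none extreme
    assert (z < 3).mean() >= 0.95
    assert z.max() < 4.5
    assert np.mean(z) < 1.5


def test_record_invariants_hold(paper_like_cohort):
    df = paper_like_cohort
    validate_cohort(df)  # should not raise
    assert (df["age_years"] >= 65).all()
    fup = df["followup_end_years"].to_numpy()
    for name in ("dementia", "zoster", "mortality", "negative_control"):
        t = df[f"{name}_time"].to_numpy()
        e = df[f"{name}_event"].to_numpy()
        assert (t <= fup + 1e-9).all()
        assert np.allclose(t[e == 0], fup[e == 0])


def test_followup_medians_are_era_dependent(paper_like_cohort):
    med = paper_like_cohort.groupby("era")["followup_end_years"].median()
    assert med["comparator"] > 5.5
    assert 3.4 < med["primary"] < 4.8


def test_determinism_same_seed_byte_identical(tmp_path):
    cfg = simple_config(n=200, seed=9)
    a, b = generate_cohorts(cfg), generate_cohorts(cfg)
    pd.testing.assert_frame_equal(a, b)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort_table(a, pa)
    write_cohort_table(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_named_streams_isolate_concerns():
    # adding a covariate must not perturb event draws
    base = simple_config(n=300, seed=4)
    with_cov = SimulationConfig.from_dict({**base.to_dict(), "covariates": [
        {"name": "x", "kind": "binary", "by_era": {"comparator": 0.3, "primary": 0.3}}
    ]})
    a = generate_cohorts(base)
    b = generate_cohorts(with_cov)
    assert np.array_equal(a["evt_time"], b["evt_time"])
    assert np.array_equal(a["sex"], b["sex"])


def test_roundtrip_identity(tmp_path, paper_like_cohort):
    df = paper_like_cohort.iloc[:1000]
    path = tmp_path / "cohort.csv"
    write_cohort_table(df, path)
    back = read_cohort_table(path)
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), df.reset_index(drop=True), check_dtype=False
    )


def test_empty_cohort_roundtrip(tmp_path):
    df = generate_cohorts(simple_config(n=5)).iloc[:0]
    path = tmp_path / "empty.csv"
    write_cohort_table(df, path)
    back = read_cohort_table(path)
    assert len(back) == 0
    assert list(back.columns) == list(df.columns)


def test_parse_errors_name_offending_row(tmp_path, paper_like_cohort):
    df = paper_like_cohort.iloc[:10].copy()
    df.loc[df.index[3], "era"] = "mystery"
    with pytest.raises(ConfigError, match="era"):
        validate_cohort(df)
    df2 = paper_like_cohort.iloc[:10].copy()
    df2.loc[df2.index[2], "dementia_time"] = -1.0
    with pytest.raises(ConfigError, match="negative"):
        validate_cohort(df2)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        CovariateSpec("bad", "binary", {"comparator": 1.4, "primary": 0.2})
    with pytest.raises(ConfigError):
        OutcomeSpec("bad", baseline_hazard=PiecewiseConstant((6.0,), (-0.1,)))
    with pytest.raises(ConfigError):
        simple_config(n=0)


def test_patient_record_view(paper_like_cohort):
    recs = to_records(paper_like_cohort.iloc[:5])
    assert len(recs) == 5
    r = recs[0]
    assert r.era in ("comparator", "primary")
    assert set(r.outcome_events) == {"dementia", "zoster", "mortality", "negative_control"}
    t, e = r.outcome_events["dementia"]
    assert t <= r.followup_end_years + 1e-9


def test_yaml_config_roundtrip(tmp_path):
    cfg = paper_like(100, 120, seed=3, n_comorbidities=3)
    path = tmp_path / "scenario.yaml"
    cfg.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    pd.testing.assert_frame_equal(generate_cohorts(cfg), generate_cohorts(back))
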