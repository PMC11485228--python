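"""Time-varying hazard ratio from the spline log-cumulative-hazard model.

Uses a scenario variant with a strong waning era effect (HR rising from
~0.55 toward 1 across follow-up) so the fitted shape is visible at this
cohort size, fits the flexible parametric model end-to-end after
matching, and evaluates HR(t) with pointwise CIs.
"""
import numpy as np
import pandas as pd

import natexp
from natexp import OutcomeSpec, PiecewiseConstant, SimulationConfig
from natexp.pipeline import default_covariates
from natexp.scenarios import paper_like

base = paper_like(8000, 9600, seed=7)
strong_waning = PiecewiseConstant(
    (1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    tuple(np.log([0.55, 0.64, 0.73, 0.82, 0.91, 1.0])),
)
outcomes = tuple(
    OutcomeSpec(o.name, o.baseline_hazard, o.log_hr_covariates,
                strong_waning if o.name == "dementia" else o.era_log_hr,
                0.0 if o.name == "dementia" else o.sex_interaction_log_hr,
                o.is_mortality)
    for o in base.outcomes
)
cfg = SimulationConfig(**{**base.__dict__, "outcomes": outcomes})
cohort = natexp.generate_cohorts(cfg)

model = natexp.fit_propensity(cohort, default_covariates(cohort))
era = pd.Series(cohort["era"].to_numpy(), index=cohort["patient_id"].to_numpy())
matched = natexp.match_nearest(era, model.scores, caliper=0.1, seed=7)

sub = cohort[cohort["patient_id"].isin(set(matched.matched_ids()))]
sub = sub[sub["dementia_time"] > 0.25]  # 3-month landmark
t = sub["dementia_time"].to_numpy() - 0.25
e = sub["dementia_event"].to_numpy()
g = (sub["era"] == "primary").to_numpy(int)

fs = natexp.flexsurv_fit(t, e, g, df_baseline=2, df_group=2)
print(f"flexible fit: df=(2,2), loglik={fs.loglik:.1f}, AIC={fs.aic:.1f}")
hr = natexp.time_varying_hr(fs, np.array([0.75, 1.75, 2.75, 3.75, 4.75, 5.25]))
for ti, h, lo, hi in zip(hr.times, hr.hr, hr.ci_low, hr.ci_high):
    print(f"  t = {ti + 0.25:4.1f} y: HR = {h:.2f} ({lo:.2f}-{hi:.2f})")
print(
    "\nThe generative era effect is strongest right after the step change"
    "\nand wanes over follow-up, so HR(t) starts well below 1 and climbs"
    "\ntoward the null by the 6-year horizon."
)
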