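"""Propensity-score matching and covariate balance.

Fits the era-membership logistic model, matches 1:1 with a 0.1 caliper
over a randomized processing order, and reports standardized mean
differences before and after matching (< 0.1 = well matched).
"""
import pandas as pd

import natexp
from natexp.pipeline import default_covariates
from natexp.scenarios import paper_like

cohort = natexp.generate_cohorts(paper_like(4000, 4800, seed=7))
covariates = default_covariates(cohort)

model = natexp.fit_propensity(cohort, covariates)
era = pd.Series(cohort["era"].to_numpy(), index=cohort["patient_id"].to_numpy())
matched = natexp.match_nearest(era, model.scores, caliper=0.1, seed=7)
balance = natexp.balance_table(cohort, covariates, matched)

print(f"matched pairs: {matched.n_pairs}")
worst = balance.sort_values("smd_before", ascending=False).head(6)
print("\nMost imbalanced covariates before matching:")
print(worst.round(3).to_string(index=False))
print(f"\nmax SMD after matching: {balance['smd_after'].max():.3f}")
print(
    "\nDrifted covariates (SMD > 0.15 before matching) are balanced to"
    "\nSMD < 0.1 after matching, the conventional well-matched threshold."
)
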