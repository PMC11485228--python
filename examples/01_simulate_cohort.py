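"""Generate a synthetic two-era cohort and inspect its structure.

The scenario emulates a step-change natural experiment: a comparator
era (entry over 36 months before the switch) and a primary era (after),
with covariate drift between eras and era-dependent follow-up.
"""
import natexp
from natexp.scenarios import paper_like

cfg = paper_like(n_comparator=4000, n_primary=4800, seed=7)
cohort = natexp.generate_cohorts(cfg)

print(f"{len(cohort)} patients, {cohort.shape[1]} columns")
print("\nMedian follow-up by era (years):")
print(cohort.groupby("era")["followup_end_years"].median().round(2).to_string())
print("\n6-year dementia event fraction by era:")
print(cohort.groupby("era")["dementia_event"].mean().round(4).to_string())
print("\nExample of covariate drift (influenza_vaccine prevalence):")
print(cohort.groupby("era")["influenza_vaccine"].mean().round(3).to_string())

natexp.write_cohort_table(cohort, "scratch_cohort.csv")
print("\nWrote scratch_cohort.csv (delete at will).")
print(
    "\nThe comparator era has ~6 y of follow-up while the primary era has a"
    "\nmedian around 4 y (later entry against a fixed data cutoff); the raw"
    "\nevent fractions differ both because of the era effect and because of"
    "\nthe shorter primary-era follow-up -- which is why the analysis uses"
    "\ncensoring-aware RMTL estimates, not raw fractions."
)
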