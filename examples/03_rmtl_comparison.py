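"""Restricted-mean-time-lost comparison between eras.

Runs the full primary analysis (match, landmark at 3 months, horizon
6 years) and prints the RMTL ratio with CI, the z-test P value and the
additional event-free days among those affected.
"""
import natexp
from natexp.scenarios import paper_like

cohort = natexp.generate_cohorts(paper_like(6000, 7200, seed=7))
row = natexp.run_analysis(
    cohort, natexp.AnalysisConfig(outcome="dementia", analysis_id="primary", seed=7)
)

print(f"matched pairs:      {row['n_comparator']}")
print(f"RMTL ratio:         {row['rmtl_ratio']:.3f} "
      f"({row['ci_low']:.3f}-{row['ci_high']:.3f}), P = {row['p_value']:.2e}")
print(f"additional days:    {row['additional_days']:.0f} "
      f"({row['ad_ci_low']:.0f}-{row['ad_ci_high']:.0f})")
print(f"PH test P:          {row['ph_p']:.3f}")
print(
    "\nAn RMTL ratio below 1 means the primary-era cohort lost less"
    "\nevent-free time before the 6-year horizon; the additional-days"
    "\nfigure translates the RMTL difference into extra diagnosis-free"
    "\ndays among the people who do develop the outcome."
)
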